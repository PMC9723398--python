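"""Reading and writing the tab-separated table dialects used by the pipeline.

Canonical dialects (all TSV with a header row):

* phosphosite tables — ``site_id, protein_id, amino_acid, position,
  sequence_window`` followed by ``ratio_<condition>_rep<k>`` columns; absent
  measurements are empty cells;
* edge tables — ``node_a, node_b, score_experiments, score_databases,
  relation`` (relation empty for plain PPI edges);
* motif libraries — ``kinase<TAB>pattern`` lines (see :mod:`.motifs`);
* ground truth — JSON.

Both table readers accept a column-mapping so exports with other headers
(e.g. a MaxQuant "Phospho (STY)Sites"-style table, or a STRING TSV export)
can be ingested without editing the file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError
from .motifs import MotifDefinition, parse_motif_library
from .network import InteractionEdge
from .simulate import GroundTruth


def write_phosphosite_table(table: pd.DataFrame, path) -> None:
    # %.17g round-trips float64 exactly, so written tables reload losslessly
    table.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_phosphosite_table(path, column_map: Mapping | None = None) -> pd.DataFrame:
    """Read a phosphosite TSV, optionally remapping foreign column headers.

    ``column_map`` maps canonical identity columns to the file's headers
    (``{"site_id": "id", "protein_id": "Protein", ...}``) and may carry a
    ``"ratios"`` entry of the form ``{condition: {replicate_number:
    source_column}}`` for per-replicate ratio columns (e.g. MaxQuant's
    ``Ratio H/L normalized <experiment>`` headers).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if column_map:
        rename = {}
        for canonical, source in column_map.items():
            if canonical == "ratios":
                for condition, reps in source.items():
                    for rep, source_column in reps.items():
                        rename[source_column] = f"ratio_{condition}_rep{rep}"
            else:
                rename[source] = canonical
        missing = [c for c in rename if c not in df.columns]
        if missing:
            raise ConfigError(f"{path}: mapped columns not found: {missing}")
        df = df.rename(columns=rename)
    required = ["site_id", "protein_id", "sequence_window"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ConfigError(f"{path}: missing required columns {absent}")
    return df


def write_edge_table(edges: Iterable[InteractionEdge], path) -> None:
    rows = [
        {
            "node_a": e.node_a,
            "node_b": e.node_b,
            "score_experiments": e.experiments,
            "score_databases": e.databases,
            "relation": e.relation or "",
        }
        for e in edges
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "score_experiments", "score_databases", "relation"]
    ).to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_edge_table(path, column_map: Mapping | None = None) -> list[InteractionEdge]:
    """Read an edge TSV into validated edges (STRING-style exports via column_map)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    for required in ("node_a", "node_b"):
        if required not in df.columns:
            raise ConfigError(f"{path}: missing required column {required!r}")
    edges = []
    for row in df.itertuples(index=False):
        relation = getattr(row, "relation", None)
        if pd.isna(relation) or relation == "":
            relation = None
        experiments = getattr(row, "score_experiments", None)
        databases = getattr(row, "score_databases", None)
        edges.append(
            InteractionEdge(
                node_a=str(row.node_a),
                node_b=str(row.node_b),
                experiments=None if pd.isna(experiments) else float(experiments),
                databases=None if pd.isna(databases) else float(databases),
                relation=relation,
            )
        )
    return edges


def read_motif_library(path) -> list[MotifDefinition]:
    return parse_motif_library(Path(path).read_text())


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
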