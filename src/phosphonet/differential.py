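"""Differential phosphosite and phosphoprotein calling from SILAC ratio tables.

The input is a site-level quantification table (one row per phosphosite) with
per-replicate SILAC ratio columns named ``ratio_<condition>_rep<k>``. The
analysis is threshold-based, mirroring the standard SILAC workflow:

1. per condition-replicate column, ratios are normalized so the median of
   log2 ratios is zero;
2. a site is considered quantified for a comparison only if present in at
   least ``min_present`` of ``n_replicates`` replicates (default 2 of 3);
3. the geometric mean of the present replicate ratios is thresholded —
   strictly > 1.5 is called up, strictly < 0.67 down (a >50% change), and
   anything between is unchanged;
4. a protein is differentially phosphorylated iff at least one of its sites
   is regulated; conflicting site directions are reported, not netted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

RATIO_COLUMN_RE = re.compile(r"^ratio_(?P<condition>.+)_rep(?P<rep>\d+)$")

#: identity columns every phosphosite table carries.
SITE_COLUMNS = ["site_id", "protein_id", "amino_acid", "position", "sequence_window"]

LABEL_UP = "up"
LABEL_DOWN = "down"
LABEL_UNCHANGED = "unchanged"
LABEL_NOT_QUANTIFIED = "not_quantified"


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and replicate-presence thresholds for regulation calls."""

    up_threshold: float = 1.5
    down_threshold: float = 0.67
    min_present: int = 2
    n_replicates: int = 3

    def __post_init__(self):
        if not self.down_threshold < 1 < self.up_threshold:
            raise ConfigError(
                "thresholds must satisfy down_threshold < 1 < up_threshold "
                f"(got down_threshold={self.down_threshold}, up_threshold={self.up_threshold})"
            )
        if not 1 <= self.min_present <= self.n_replicates:
            raise ConfigError(
                f"min_present={self.min_present} must be in 1..n_replicates={self.n_replicates}"
            )


@dataclass(frozen=True)
class ComparisonDesign:
    """One constitutive or agonist-induced comparison.

    Per replicate, the comparison ratio is the numerator condition's SILAC
    ratio divided by the denominator condition's — making the channel pairing
    of each comparison explicit rather than implied by column naming.
    """

    name: str
    numerator_condition: str
    denominator_condition: str
    receptor: str = ""

    def __post_init__(self):
        if self.numerator_condition == self.denominator_condition:
            raise ConfigError(
                f"comparison {self.name!r}: numerator_condition and denominator_condition "
                "must differ"
            )


def ratio_columns(table: pd.DataFrame) -> dict[str, list[str]]:
    """Map condition label -> its replicate ratio columns, in replicate order."""
    by_condition: dict[str, list[tuple[int, str]]] = {}
    for column in table.columns:
        m = RATIO_COLUMN_RE.match(column)
        if m:
            by_condition.setdefault(m["condition"], []).append((int(m["rep"]), column))
    return {cond: [c for _, c in sorted(cols)] for cond, cols in by_condition.items()}


def normalize_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Center each condition-replicate ratio column at median log2 ratio zero.

    Absent (NaN) measurements are untouched and row order is preserved. The
    operation is idempotent and removes any constant multiplicative bias in a
    column (e.g. unequal channel mixing).
    """
    result = table.copy()
    for condition, columns in ratio_columns(table).items():
        for column in columns:
            values = result[column].astype(float)
            present = values.notna()
            if not present.any():
                raise ConfigError(f"column {column!r} has no quantified values to normalize")
            if (values[present] <= 0).any():
                bad = result.loc[present & (values <= 0)]
                site = bad.iloc[0].get("site_id", bad.index[0])
                raise ConfigError(
                    f"column {column!r}: nonpositive ratio for record {site!r}"
                )
            median_log2 = np.median(np.log2(values[present]))
            result[column] = values / (2.0**median_log2)
    return result


def comparison_ratios(table: pd.DataFrame, comparison: ComparisonDesign) -> pd.DataFrame:
    """Per-replicate comparison ratios (numerator/denominator), NaN if either absent."""
    columns = ratio_columns(table)
    for condition in (comparison.numerator_condition, comparison.denominator_condition):
        if condition not in columns:
            raise ConfigError(
                f"comparison {comparison.name!r}: condition {condition!r} not in table "
                f"(available: {sorted(columns)})"
            )
    num_cols = columns[comparison.numerator_condition]
    den_cols = columns[comparison.denominator_condition]
    if len(num_cols) != len(den_cols):
        raise ConfigError(
            f"comparison {comparison.name!r}: replicate counts differ between conditions"
        )
    out = {}
    for k, (nc, dc) in enumerate(zip(num_cols, den_cols), start=1):
        out[f"rep{k}"] = table[nc].astype(float) / table[dc].astype(float)
    return pd.DataFrame(out, index=table.index)


def filter_by_presence(
    table: pd.DataFrame, thresholds: Thresholds, comparison: ComparisonDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a table into (quantified, not_quantified) for one comparison.

    A site is positively quantified iff it is present in at least
    ``min_present`` replicates of the comparison; the remainder is returned,
    not silently dropped.
    """
    n_present = comparison_ratios(table, comparison).notna().sum(axis=1)
    keep = n_present >= thresholds.min_present
    return table.loc[keep], table.loc[~keep]


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(ln v)) of a nonempty sequence of positive ratios."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ConfigError("geometric mean of an empty sequence is undefined")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ConfigError(f"geometric mean requires positive finite values, got {list(arr)}")
    return float(np.exp(np.mean(np.log(arr))))


def call_regulation(gm_ratio: float, thresholds: Thresholds = Thresholds()) -> str:
    """Label a geometric-mean ratio: strictly >up_threshold is up, strictly
    <down_threshold is down, anything between (boundaries included) unchanged."""
    if not gm_ratio > 0:
        raise ConfigError(f"gm_ratio must be positive, got {gm_ratio}")
    if gm_ratio > thresholds.up_threshold:
        return LABEL_UP
    if gm_ratio < thresholds.down_threshold:
        return LABEL_DOWN
    return LABEL_UNCHANGED


def call_sites(
    table: pd.DataFrame, comparison: ComparisonDesign, thresholds: Thresholds
) -> pd.DataFrame:
    """Site-level regulation calls for one comparison.

    Returns one row per input site: site_id, protein_id, comparison,
    n_present, gm_ratio (NaN when not quantified) and label. The geometric
    mean uses only the present replicates of sites passing the presence
    filter.
    """
    if table["site_id"].duplicated().any():
        dup = table.loc[table["site_id"].duplicated(), "site_id"].iloc[0]
        raise ConfigError(f"duplicate site_id {dup!r} for comparison {comparison.name!r}")
    ratios = comparison_ratios(table, comparison)
    values = ratios.to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] <= 0):
        raise ConfigError(f"comparison {comparison.name!r}: nonpositive ratio encountered")
    n_present = np.isfinite(values).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_sum = np.nansum(np.where(np.isfinite(values), np.log(values), np.nan), axis=1)
        gm = np.exp(log_sum / n_present)  # NaN when nothing is present
    quantified = n_present >= thresholds.min_present
    labels = np.where(
        ~quantified,
        LABEL_NOT_QUANTIFIED,
        np.where(
            gm > thresholds.up_threshold,
            LABEL_UP,
            np.where(gm < thresholds.down_threshold, LABEL_DOWN, LABEL_UNCHANGED),
        ),
    )
    return pd.DataFrame(
        {
            "site_id": table["site_id"].to_numpy(),
            "protein_id": table["protein_id"].to_numpy(),
            "comparison": comparison.name,
            "n_present": n_present,
            "gm_ratio": np.where(quantified, gm, np.nan),
            "label": labels,
        }
    )


def call_proteins(site_calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate site calls to the protein level, one row per (protein, comparison).

    A protein is regulated iff at least one of its quantified sites is; the
    ``directions`` field lists the distinct directions among its regulated
    sites (``up``, ``down`` or ``up|down`` — conflicting sites are reported,
    not resolved to a net direction).
    """
    rows = []
    for (protein, comparison), group in site_calls.groupby(
        ["protein_id", "comparison"], sort=True
    ):
        labels = group["label"]
        n_up = int((labels == LABEL_UP).sum())
        n_down = int((labels == LABEL_DOWN).sum())
        n_quantified = int((labels != LABEL_NOT_QUANTIFIED).sum())
        directions = "|".join(d for d, n in (("up", n_up), ("down", n_down)) if n > 0)
        if n_quantified == 0:
            label = LABEL_NOT_QUANTIFIED
        elif directions:
            label = directions
        else:
            label = LABEL_UNCHANGED
        rows.append(
            {
                "protein_id": protein,
                "comparison": comparison,
                "n_sites": len(group),
                "n_quantified": n_quantified,
                "n_up": n_up,
                "n_down": n_down,
                "regulated": bool(directions),
                "directions": directions,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "comparison",
            "n_sites",
            "n_quantified",
            "n_up",
            "n_down",
            "regulated",
            "directions",
            "label",
        ],
    )


def call_sites_and_proteins(
    table: pd.DataFrame,
    design: Iterable[ComparisonDesign],
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run site- and protein-level regulation calls for every comparison."""
    site_frames = [call_sites(table, comparison, thresholds) for comparison in design]
    site_calls = pd.concat(site_frames, ignore_index=True)
    protein_calls = call_proteins(site_calls)
    return site_calls, protein_calls


def _direction_sets(calls: pd.DataFrame, id_column: str) -> dict[str, dict[str, frozenset]]:
    """comparison -> {identifier -> set of regulated directions}, regulated only."""
    out: dict[str, dict[str, frozenset]] = {}
    directions_col = "directions" if "directions" in calls.columns else None
    for _, row in calls.iterrows():
        if directions_col:
            dirs = frozenset(d for d in str(row[directions_col]).split("|") if d in ("up", "down"))
        else:
            dirs = frozenset([row["label"]]) if row["label"] in (LABEL_UP, LABEL_DOWN) else frozenset()
        if dirs:
            out.setdefault(row["comparison"], {})[row[id_column]] = dirs
    return out


def summarize_sets(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    receptor_a: str = "A",
    receptor_b: str = "B",
    id_column: str = "site_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct/shared regulated-set summary and up/down kinetics for a receptor pair.

    Works on site calls (``id_column='site_id'``) or protein calls
    (``id_column='protein_id'``). Per comparison: counts of identifiers
    regulated only in A, only in B, shared with a coherent direction (the
    direction sets intersect) and shared with discordant directions. The
    kinetics table counts up/down identifiers per receptor and comparison.
    """
    comps_a = set(calls_a["comparison"])
    comps_b = set(calls_b["comparison"])
    if comps_a != comps_b:
        raise ConfigError(
            f"mismatched comparison names between receptors: {sorted(comps_a ^ comps_b)}"
        )
    dirs_a = _direction_sets(calls_a, id_column)
    dirs_b = _direction_sets(calls_b, id_column)
    overlap_rows, kinetics_rows = [], []
    for comparison in sorted(comps_a):
        a = dirs_a.get(comparison, {})
        b = dirs_b.get(comparison, {})
        shared = set(a) & set(b)
        coherent = sum(1 for i in shared if a[i] & b[i])
        overlap_rows.append(
            {
                "comparison": comparison,
                "receptor_a": receptor_a,
                "receptor_b": receptor_b,
                "unique_to_a": len(set(a) - set(b)),
                "unique_to_b": len(set(b) - set(a)),
                "shared_coherent": coherent,
                "shared_discordant": len(shared) - coherent,
            }
        )
        for receptor, dirs in ((receptor_a, a), (receptor_b, b)):
            kinetics_rows.append(
                {
                    "receptor": receptor,
                    "comparison": comparison,
                    "n_up": sum(1 for d in dirs.values() if "up" in d),
                    "n_down": sum(1 for d in dirs.values() if "down" in d),
                    "n_regulated": len(dirs),
                }
            )
    return pd.DataFrame(overlap_rows), pd.DataFrame(kinetics_rows)
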