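"""Kinase attribution of phosphosites by consensus sequence-motif matching.

A kinase consensus motif is a set of position-specific residue constraints on
the 13-mer sequence window (offsets -6..+6) centered on the phosphoacceptor,
e.g. the basophilic PKA consensus ``R-R-x-S*`` (arginines at -3/-2, serine
acceptor). Matching is purely boolean and count-based: a regulated phosphosite
is attributed to every kinase whose motif its window satisfies, and relative
kinase activity between two receptors is compared by the ratio of the
percentage of motif counts each kinase receives.

Motif dialect (one motif per line, tab-separated)::

    PKA<TAB>R-R-x-S*
    CDK1<TAB>S*-P-x-[KR]

Positions are dash-separated; ``x`` is a wildcard, ``[RK]`` an allowed-residue
set, and the ``*`` suffix marks the phosphoacceptor (which must be S, T or Y).
Lines starting with ``#`` and blank lines are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, MotifParseError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PHOSPHOACCEPTORS = frozenset("STY")
#: placeholder for window positions beyond a protein terminus; never matches
#: a non-wildcard motif position.
PADDING = "_"
WINDOW_LENGTH = 13
CENTER_INDEX = 6

#: Illustrative default consensus library (well-known textbook motifs). This is
#: a stand-in for whatever curated motif database a given study used; kinase
#: attributions on real data depend entirely on the library supplied.
DEFAULT_MOTIF_LIBRARY_TEXT = """\
# kinase\tpattern   (x = wildcard, * = phosphoacceptor)
PKA\tR-R-x-S*
AKT1\tR-x-R-x-x-S*
CK2\tS*-x-x-E
CDK1\tS*-P-x-[KR]
MAPK1\tP-x-S*-P
GSK3B\tS*-x-x-x-S
SRC\t[DE]-x-x-Y*
"""


@dataclass(frozen=True)
class MotifDefinition:
    """A kinase consensus pattern over window offsets -6..+6.

    ``constraints`` maps a nonzero offset to the set of residues allowed
    there; offsets absent from the mapping are wildcards. ``center_residues``
    is the subset of {S, T, Y} the kinase phosphorylates.
    """

    kinase: str
    constraints: Mapping[int, frozenset]
    center_residues: frozenset
    pattern: str = ""

    def __post_init__(self):
        if not self.center_residues <= PHOSPHOACCEPTORS:
            raise ConfigError(
                f"motif {self.kinase!r}: center residues {set(self.center_residues)} "
                "must be a subset of {S, T, Y}"
            )
        if not self.constraints:
            raise ConfigError(
                f"motif {self.kinase!r}: needs at least one constrained position "
                "besides the phosphoacceptor"
            )
        for offset, allowed in self.constraints.items():
            if offset == 0 or not -CENTER_INDEX <= offset <= CENTER_INDEX:
                raise ConfigError(
                    f"motif {self.kinase!r}: offset {offset} outside -6..+6 or zero"
                )
            if not allowed or not frozenset(allowed) <= AMINO_ACIDS:
                raise ConfigError(
                    f"motif {self.kinase!r}: invalid residue set at offset {offset}"
                )


def _parse_token(token: str, line_number: int) -> frozenset | None:
    """One dash-separated position -> residue set, or None for a wildcard."""
    if token == "x":
        return None
    if token.startswith("[") and token.endswith("]"):
        residues = frozenset(token[1:-1])
    else:
        residues = frozenset(token)
        if len(token) != 1:
            raise MotifParseError(line_number, f"malformed position token {token!r}")
    bad = residues - AMINO_ACIDS
    if bad or not residues:
        raise MotifParseError(
            line_number, f"residues {sorted(bad) or '[]'} in {token!r} are not amino acids"
        )
    return residues


def parse_motif_library(text: str) -> list[MotifDefinition]:
    """Parse the plain-text motif dialect into validated motif definitions.

    Raises :class:`MotifParseError` (with line number) on a missing ``*``
    phosphoacceptor mark, residues outside the 20 amino acids, or duplicate
    (kinase, pattern) pairs.
    """
    motifs: list[MotifDefinition] = []
    seen: set[tuple[str, str]] = set()
    for line_number, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MotifParseError(line_number, "expected 'kinase<TAB>pattern'")
        kinase, pattern = parts[0].strip(), parts[1].strip()
        tokens = pattern.split("-")
        center_position = [i for i, t in enumerate(tokens) if t.endswith("*")]
        if len(center_position) != 1:
            raise MotifParseError(
                line_number, f"pattern {pattern!r} must mark exactly one position with '*'"
            )
        if len(tokens) > WINDOW_LENGTH:
            raise MotifParseError(line_number, f"pattern {pattern!r} longer than 13 positions")
        center_idx = center_position[0]
        constraints: dict[int, frozenset] = {}
        center_residues: frozenset = frozenset()
        for i, token in enumerate(tokens):
            offset = i - center_idx
            if offset == 0:
                token = token[:-1]
                allowed = _parse_token(token, line_number)
                if allowed is None or not allowed <= PHOSPHOACCEPTORS:
                    raise MotifParseError(
                        line_number, f"phosphoacceptor {token!r} must be one or more of S/T/Y"
                    )
                center_residues = allowed
            else:
                if not -CENTER_INDEX <= offset <= CENTER_INDEX:
                    raise MotifParseError(line_number, f"offset {offset} outside window -6..+6")
                allowed = _parse_token(token, line_number)
                if allowed is not None:
                    constraints[offset] = allowed
        if not constraints:
            raise MotifParseError(
                line_number,
                f"motif {kinase!r} has no constrained position besides the phosphoacceptor",
            )
        key = (kinase, pattern)
        if key in seen:
            raise MotifParseError(line_number, f"duplicate motif {kinase!r} / {pattern!r}")
        seen.add(key)
        motifs.append(
            MotifDefinition(
                kinase=kinase,
                constraints=constraints,
                center_residues=center_residues,
                pattern=pattern,
            )
        )
    return motifs


def default_motif_library() -> list[MotifDefinition]:
    """The built-in illustrative consensus library."""
    return parse_motif_library(DEFAULT_MOTIF_LIBRARY_TEXT)


def match_motif(window: str, motif: MotifDefinition) -> bool:
    """True iff a 13-mer sequence window satisfies a kinase motif.

    The window center must be in the motif's acceptor set and every
    constrained offset's residue must be in its allowed set; the terminal
    padding character never satisfies a constrained position.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(
            f"sequence window must have length {WINDOW_LENGTH}, got {len(window)} ({window!r})"
        )
    if window[CENTER_INDEX] not in motif.center_residues:
        return False
    for offset, allowed in motif.constraints.items():
        if window[CENTER_INDEX + offset] not in allowed:
            return False
    return True


@dataclass
class MotifCountTable:
    """Per-kinase counts of regulated phosphosites matching each motif.

    ``counts`` maps (kinase, group) to the number of regulated sites whose
    window matches the kinase's motif, where *group* is any hashable label
    (typically a time point). ``totals`` maps group to the number of
    (site, kinase) attributions — a site matching two kinases contributes two.
    """

    receptor: str
    counts: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    kinases: tuple = ()
    groups: tuple = ()

    def count(self, kinase: str, group: Hashable) -> int:
        return self.counts.get((kinase, group), 0)

    def total(self, group: Hashable) -> int:
        return self.totals.get(group, 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (receptor, group, kinase, count, group_total) table."""
        rows = [
            {
                "receptor": self.receptor,
                "group": group,
                "kinase": kinase,
                "count": self.count(kinase, group),
                "group_total": self.total(group),
            }
            for group in self.groups
            for kinase in self.kinases
        ]
        return pd.DataFrame(rows, columns=["receptor", "group", "kinase", "count", "group_total"])


def count_motifs(
    windows_by_group: Mapping[Hashable, Sequence[str]],
    motifs: Iterable[MotifDefinition],
    receptor: str = "",
) -> MotifCountTable:
    """Count motif matches among regulated-site windows, per group.

    A site counts once toward every kinase whose motif it matches
    (deduplicated per kinase even if the kinase has several motifs in the
    library); the per-group total is the number of (site, kinase)
    attributions.
    """
    motifs = list(motifs)
    if not motifs:
        raise ConfigError("motif library is empty")
    kinases = tuple(dict.fromkeys(m.kinase for m in motifs))
    counts: dict = {}
    totals: dict = {}
    for group, windows in windows_by_group.items():
        totals.setdefault(group, 0)
        for window in windows:
            matched = {m.kinase for m in motifs if match_motif(window, m)}
            for kinase in matched:
                counts[(kinase, group)] = counts.get((kinase, group), 0) + 1
            totals[group] += len(matched)
    return MotifCountTable(
        receptor=receptor,
        counts=counts,
        totals=totals,
        kinases=kinases,
        groups=tuple(windows_by_group),
    )


def motif_percentage_ratio(
    counts_a: MotifCountTable,
    counts_b: MotifCountTable,
    kinase: str,
    group: Hashable,
) -> float:
    """Ratio of the percentage of motif counts attributed to one kinase.

    Returns [count_A(k)/total_A] / [count_B(k)/total_B]. A value of 1 means
    equal relative attribution in the two receptors. Sentinels: +inf when the
    kinase is attributed only in A, NaN when it is attributed in neither.
    """
    total_a, total_b = counts_a.total(group), counts_b.total(group)
    if total_a <= 0 or total_b <= 0:
        raise ConfigError(
            f"group {group!r}: both receptors need a nonzero attribution total "
            f"(got {total_a} and {total_b})"
        )
    pct_a = counts_a.count(kinase, group) / total_a
    pct_b = counts_b.count(kinase, group) / total_b
    if pct_b == 0:
        return math.inf if pct_a > 0 else math.nan
    return pct_a / pct_b


def percentage_ratio_table(
    counts_a: MotifCountTable, counts_b: MotifCountTable
) -> pd.DataFrame:
    """All kinases x shared groups percentage ratios, long format."""
    kinases = tuple(dict.fromkeys(counts_a.kinases + counts_b.kinases))
    groups = [g for g in counts_a.groups if g in set(counts_b.groups)]
    rows = []
    for group in groups:
        for kinase in kinases:
            rows.append(
                {
                    "group": group,
                    "kinase": kinase,
                    "receptor_a": counts_a.receptor,
                    "receptor_b": counts_b.receptor,
                    "count_a": counts_a.count(kinase, group),
                    "count_b": counts_b.count(kinase, group),
                    "percentage_ratio": motif_percentage_ratio(
                        counts_a, counts_b, kinase, group
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "kinase",
            "receptor_a",
            "receptor_b",
            "count_a",
            "count_b",
            "percentage_ratio",
        ],
    )


def count_kinases_more_active(
    counts_a: MotifCountTable, counts_b: MotifCountTable, group: Hashable
) -> int:
    """Number of kinases relatively more attributed in receptor A than B.

    "More active with A" is a percentage ratio strictly greater than 1
    (+inf qualifies; NaN — attributed in neither — does not).
    """
    kinases = dict.fromkeys(counts_a.kinases + counts_b.kinases)
    n = 0
    for kinase in kinases:
        ratio = motif_percentage_ratio(counts_a, counts_b, kinase, group)
        if ratio > 1:
            n += 1
    return n
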