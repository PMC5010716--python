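"""Gapped-motif scanning and group-enrichment statistics.

A "gapped motif" (a short linear motif, SLiM) is a pattern of residues in
fixed relative positions: literal residues, wildcards, and residue classes,
written in the compact grammar ``LLXXE`` or ``[DE]LLX[ST]`` (X = any
residue, ``[...]`` = any member of the class). Composite patterns are
conjunctions of motifs that must all occur in one domain, optionally in
N-to-C order (e.g. the two-motif signature ``[DE]LLX[ST] + [DE]XX[AV]XWL``
in p53 TAD2).

Enrichment of a motif in one species group versus another is tested with
Fisher's exact test on presence/absence counts; a 2x2 variant with a
noncentral (odds-ratio != 1) null supports designs where the expected
composition is itself skewed, and a 2x3 Freeman-Halton exact test covers
three-group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_fisher

from .core_io import STANDARD_AA, Alignment, DomainFragmentSet, SpeciesRecord


class PatternError(ValueError):
    """Raised for malformed patterns or invalid contingency tables."""


# ---------------------------------------------------------------------------
# motif grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixed:
    residue: str


@dataclass(frozen=True)
class Any_:
    pass


@dataclass(frozen=True)
class ResidueClass:
    residues: frozenset[str]


Token = Fixed | Any_ | ResidueClass


@dataclass(frozen=True)
class MotifPattern:
    """A gapped motif: an ordered list of position tokens.

    ``scope`` optionally names the domain the motif is scanned in."""

    name: str
    tokens: tuple[Token, ...]
    scope: str = ""

    def __post_init__(self) -> None:
        if not self.tokens:
            raise PatternError(f"pattern {self.name!r} has no tokens")
        for t in self.tokens:
            if isinstance(t, ResidueClass):
                if not t.residues or not t.residues <= STANDARD_AA:
                    raise PatternError(
                        f"pattern {self.name!r}: residue class must be a "
                        "non-empty subset of the 20 amino acids"
                    )
            elif isinstance(t, Fixed) and t.residue not in STANDARD_AA:
                raise PatternError(
                    f"pattern {self.name!r}: {t.residue!r} is not a standard residue"
                )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class CompositePattern:
    """A conjunction of motifs scoped to one domain.

    With ``order_constraint`` the match start positions must be strictly
    increasing in motif order (N-terminal to C-terminal); overlap between
    consecutive matches is permitted.
    """

    name: str
    motifs: tuple[MotifPattern, ...]
    scope: str = ""
    order_constraint: bool = True

    def __post_init__(self) -> None:
        if len(self.motifs) < 2:
            raise PatternError(
                f"composite pattern {self.name!r} needs at least 2 motifs"
            )


def parse_pattern(text: str, name: str = "", scope: str = "") -> MotifPattern:
    """Parse the motif grammar: letters are fixed residues, ``X`` is a
    wildcard, ``[...]`` a residue class. Example: ``[DE]LLX[ST]``."""
    tokens: list[Token] = []
    i = 0
    text = text.strip()
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' in pattern {text!r}")
            members = text[i + 1 : j].upper()
            if not members:
                raise PatternError(f"empty residue class in pattern {text!r}")
            tokens.append(ResidueClass(frozenset(members)))
            i = j + 1
        elif c.upper() == "X":
            tokens.append(Any_())
            i += 1
        elif c.upper() in STANDARD_AA:
            tokens.append(Fixed(c.upper()))
            i += 1
        else:
            raise PatternError(f"unexpected character {c!r} in pattern {text!r}")
    return MotifPattern(name=name or text, tokens=tuple(tokens), scope=scope)


def render_pattern(pattern: MotifPattern) -> str:
    """Inverse of :func:`parse_pattern` (classes rendered in sorted order)."""
    parts = []
    for t in pattern.tokens:
        if isinstance(t, Fixed):
            parts.append(t.residue)
        elif isinstance(t, Any_):
            parts.append("X")
        else:
            parts.append("[" + "".join(sorted(t.residues)) + "]")
    return "".join(parts)


def _token_matches(token: Token, residue: str) -> bool:
    if isinstance(token, Fixed):
        return residue == token.residue
    if isinstance(token, Any_):
        return True
    return residue in token.residues


def scan_motif(seq: str, pattern: MotifPattern) -> list[int]:
    """All 1-based start positions where the motif matches (overlapping
    matches included). The sequence must be gap-free."""
    if "-" in seq:
        raise PatternError("scan_motif requires a gap-free sequence")
    m = len(pattern.tokens)
    hits = []
    for start in range(len(seq) - m + 1):
        if all(
            _token_matches(tok, seq[start + off])
            for off, tok in enumerate(pattern.tokens)
        ):
            hits.append(start + 1)
    return hits


def has_composite(seq: str, c: CompositePattern) -> bool:
    """True iff every motif matches; with the order constraint, some choice
    of match starts must be strictly increasing in motif order."""
    all_hits = [scan_motif(seq, m) for m in c.motifs]
    if any(not hits for hits in all_hits):
        return False
    if not c.order_constraint:
        return True
    prev = 0
    for hits in all_hits:  # greedy earliest-feasible start is optimal here
        nxt = next((h for h in hits if h > prev), None)
        if nxt is None:
            return False
        prev = nxt
    return True


def read_pattern_file(path) -> list[MotifPattern | CompositePattern]:
    """Read patterns from a TSV: ``name <TAB> scope <TAB> expression``;
    composite expressions join motifs with ``+``."""
    out: list[MotifPattern | CompositePattern] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PatternError(
                    f"{path}:{lineno}: expected 'name<TAB>scope<TAB>expression'"
                )
            name, scope, expr = (p.strip() for p in parts)
            if "+" in expr:
                motifs = tuple(
                    parse_pattern(e.strip(), name=f"{name}.{i + 1}")
                    for i, e in enumerate(expr.split("+"))
                )
                out.append(CompositePattern(name=name, motifs=motifs, scope=scope))
            else:
                out.append(parse_pattern(expr, name=name, scope=scope))
    return out


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean species x pattern table with group labels attached."""

    table: pd.DataFrame
    groups: pd.Series

    def counts(self, pattern: str, group: str) -> tuple[int, int]:
        """(#present, group size) for one pattern in one group."""
        mask = self.groups == group
        return int(self.table.loc[mask, pattern].sum()), int(mask.sum())


def presence_matrix(
    fragsets: Mapping[str, DomainFragmentSet],
    species: Sequence[SpeciesRecord],
    patterns: Sequence[MotifPattern | CompositePattern],
) -> PresenceMatrix:
    """Evaluate pattern presence per species. Each pattern is scanned in
    its scope domain's fragment (anywhere in the fragment)."""
    ids = [r.species_id for r in species]
    data: dict[str, list[bool]] = {}
    for p in patterns:
        scope = p.scope
        if scope not in fragsets:
            raise PatternError(
                f"pattern {p.name!r}: scope domain {scope!r} not among fragments"
            )
        frags = fragsets[scope]
        col = []
        for sid in ids:
            seq = frags.fragment(sid)
            if isinstance(p, CompositePattern):
                col.append(has_composite(seq, p))
            else:
                col.append(bool(scan_motif(seq, p)))
        data[p.name] = col
    table = pd.DataFrame(data, index=ids, dtype=bool)
    groups = pd.Series([r.group for r in species], index=ids, name="group")
    return PresenceMatrix(table=table, groups=groups)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _check_table(table, shape) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != shape:
        raise PatternError(f"expected a {shape} table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)) or np.any(t < 0):
            raise PatternError("table entries must be non-negative integers")
        t = t.astype(int)
    return t.astype(int)


def fisher_2x2(
    table, alternative: str = "two_sided", null_or: float = 1.0
) -> float:
    """Fisher's exact test on a 2x2 table, with an optional noncentral null.

    Rows are pattern present/absent, columns are the two groups; the tested
    cell is (present, group 1). Under the null the cell follows Fisher's
    noncentral hypergeometric distribution with odds ratio ``null_or``
    (the central hypergeometric when ``null_or == 1``); ``greater`` sums
    the upper tail, ``less`` the lower, and ``two_sided`` all outcomes with
    point probability <= that of the observation (relative tolerance 1e-12
    for ties). A zero row or column margin carries no information: p = 1
    with a warning.
    """
    t = _check_table(table, (2, 2))
    if null_or <= 0:
        raise PatternError(f"null odds ratio must be positive, got {null_or}")
    a = t[0, 0]
    row1 = t[0].sum()
    col1 = t[:, 0].sum()
    total = t.sum()
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        warnings.warn(
            "zero margin in 2x2 table: Fisher test is uninformative (p = 1)",
            stacklevel=2,
        )
        return 1.0
    dist = nchypergeom_fisher(total, row1, col1, null_or)
    if alternative == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if alternative == "less":
        return float(min(1.0, dist.cdf(a)))
    if alternative == "two_sided":
        lo = int(max(0, col1 - (total - row1)))
        hi = int(min(row1, col1))
        support = np.arange(lo, hi + 1)
        pmf = dist.pmf(support)
        p_obs = dist.pmf(a)
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))
    raise PatternError(f"unknown alternative {alternative!r}")


def fisher_2x3(table, max_total: int = 200) -> float:
    """Freeman-Halton exact test for a 2x3 table.

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable
    than the observed table (relative tolerance 1e-12 for ties).
    """
    t = _check_table(table, (2, 3))
    total = int(t.sum())
    if total > max_total:
        raise PatternError(
            f"table total {total} exceeds the enumeration bound {max_total}"
        )
    row1 = int(t[0].sum())
    cols = [int(c) for c in t.sum(axis=0)]
    if total == 0:
        return 1.0

    denom = comb(total, row1)

    def prob(a: int, b: int, c: int) -> float:
        return comb(cols[0], a) * comb(cols[1], b) * comb(cols[2], c) / denom

    p_obs = prob(int(t[0, 0]), int(t[0, 1]), int(t[0, 2]))
    p_sum = 0.0
    for a in range(min(row1, cols[0]) + 1):
        for b in range(min(row1 - a, cols[1]) + 1):
            c = row1 - a - b
            if 0 <= c <= cols[2]:
                p = prob(a, b, c)
                if p <= p_obs * (1 + 1e-12):
                    p_sum += p
    return float(min(1.0, p_sum))


def pattern_enrichment_report(
    pm: PresenceMatrix,
    comparisons: Sequence[tuple[str, str]] = (
        ("hypoxic", "non_stress"),
        ("metabolic", "non_stress"),
    ),
    three_way: tuple[str, str, str] | None = ("hypoxic", "metabolic", "non_stress"),
    alternative: str = "greater",
    screen_p: float = 0.005,
) -> pd.DataFrame:
    """Per-pattern group counts, pairwise 2x2 p-values, the 3-group 2x3
    p-value, and a screening flag (p below ``screen_p`` in the first
    comparison, the threshold used to select patterns for re-testing in a
    balanced design)."""
    rows = []
    for pat in pm.table.columns:
        row: dict[str, object] = {"pattern": pat}
        groups_needed = {g for pair in comparisons for g in pair}
        if three_way:
            groups_needed |= set(three_way)
        for g in sorted(groups_needed):
            k, n = pm.counts(pat, g)
            if n == 0:
                raise PatternError(f"group {g!r} is empty")
            row[f"{g}"] = f"{k}/{n}"
        for g1, g2 in comparisons:
            k1, n1 = pm.counts(pat, g1)
            k2, n2 = pm.counts(pat, g2)
            table = [[k1, k2], [n1 - k1, n2 - k2]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"p_{g1}_vs_{g2}"] = fisher_2x2(table, alternative=alternative)
        if three_way:
            counts = [pm.counts(pat, g) for g in three_way]
            table23 = [
                [k for k, _ in counts],
                [n - k for k, n in counts],
            ]
            row["p_2x3"] = fisher_2x3(table23)
        g1, g2 = comparisons[0]
        row["screen"] = bool(row[f"p_{g1}_vs_{g2}"] < screen_p)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classifier hand-off
# ---------------------------------------------------------------------------

def predictor_matrix(
    aln: Alignment, positions: Sequence[int], one_hot: bool = False
) -> pd.DataFrame:
    """Species x position residue table for downstream classification.

    ``positions`` are 1-based alignment columns (the informative pattern
    positions). With ``one_hot`` each column expands into one indicator per
    observed residue; gaps form their own '-' category.
    """
    for pos in positions:
        if not (1 <= pos <= aln.width):
            raise PatternError(f"column {pos} outside alignment width {aln.width}")
    data = {
        f"pos{pos}": [seq[pos - 1] for _, seq in aln] for pos in positions
    }
    df = pd.DataFrame(data, index=list(aln.ids))
    if not one_hot:
        return df
    return pd.get_dummies(df, prefix_sep="=", dtype=int)
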