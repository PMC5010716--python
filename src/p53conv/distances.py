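"""Poisson-corrected amino-acid distances and divergence-time matrices.

The sequence distance used throughout the package is the Poisson correction

    d = -ln(1 - p)

where ``p`` is the proportion of sites at which two equal-length, gap-free
fragments differ. The correction inverts the expected fraction of visibly
different sites under a Poisson process of substitutions with all sites
equally mutable, turning the observed proportion into an estimate of
substitutions per site. Ambiguity codes (X/B/Z) are treated as missing and
excluded from the comparable sites of any pair involving them.

Divergence-time matrices (in the time units of the input tree, typically
million years) are read either from a newick tree with branch lengths —
entry (i, j) is the leaf-to-leaf path length — or from a pairwise TSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import STANDARD_AA, DomainFragmentSet


class DistanceError(ValueError):
    """Raised for undefined distances or malformed matrix inputs."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances between species.

    ``name`` identifies the domain the distances were computed from (or
    ``"time"`` for divergence times); ``deletion`` records the missing-site
    policy used.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    name: str = ""
    deletion: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise DistanceError(
                f"matrix shape {v.shape} does not match {n} species ids"
            )
        if not np.all(np.isfinite(v)):
            raise DistanceError("matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise DistanceError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise DistanceError("matrix diagonal is not zero")
        if np.any(v < 0):
            raise DistanceError("matrix contains negative distances")

    def get(self, a: str, b: str) -> float:
        try:
            i, j = self.ids.index(a), self.ids.index(b)
        except ValueError as exc:
            raise DistanceError(f"species not in matrix: {exc}") from None
        return float(self.values[i, j])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            tuple(ids), self.values[np.ix_(idx, idx)], self.name, self.deletion
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="species_id")

    @classmethod
    def read_tsv(cls, path: str | Path, name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise DistanceError(f"{path}: row and column species ids differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float), name=name)

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance format, for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.values):
                fh.write(sid + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def _comparable(a: str, b: str) -> bool:
    return a in STANDARD_AA and b in STANDARD_AA


def p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Proportion of comparable sites at which two fragments differ.

    Sites where either residue is not one of the 20 standard amino acids
    (gaps, X/B/Z) are excluded from the comparison. For a single pair the
    ``pairwise`` and ``complete`` policies coincide; set-wide complete
    deletion is applied by :func:`distance_matrix`.
    """
    if deletion not in ("pairwise", "complete"):
        raise DistanceError(f"unknown deletion mode {deletion!r}")
    if len(a) != len(b):
        raise DistanceError(
            f"fragments have unequal lengths {len(a)} and {len(b)}; "
            "re-extract with complete_deletion or re-align"
        )
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if _comparable(x, y):
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise DistanceError("no comparable sites between fragments")
    return diffs / comparable


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), substitutions per site."""
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise DistanceError(
                "p-distance of 1 gives an infinite Poisson distance"
            )
        raise DistanceError(f"proportion {p} outside [0, 1)")
    return -math.log1p(-p)


def distance_matrix(
    frags: DomainFragmentSet | Mapping[str, str],
    deletion: str = "complete",
) -> DistanceMatrix:
    """Poisson-corrected distance matrix for a set of equal-length fragments.

    ``complete`` deletion first drops every site at which any fragment has a
    missing residue (X/B/Z) so all pairs are scored on the same sites — a
    no-op for fully standard fragments; ``pairwise`` deletion excludes
    missing sites pair by pair.
    """
    if isinstance(frags, DomainFragmentSet):
        name = frags.domain
        items = dict(frags.fragments)
        mode = frags.mode
    else:
        name = ""
        items = dict(frags)
        mode = ""
    if deletion not in ("pairwise", "complete"):
        raise DistanceError(f"unknown deletion mode {deletion!r}")
    ids = tuple(items)
    if len(ids) < 2:
        raise DistanceError("need at least 2 species for a distance matrix")
    seqs = [items[i] for i in ids]
    length = len(seqs[0])
    for sid, s in items.items():
        if len(s) != length:
            raise DistanceError(
                f"fragment lengths differ (species {sid!r}: {len(s)} vs {length}); "
                + (
                    "per_sequence_degap fragments must be re-aligned before "
                    "computing distances"
                    if mode == "per_sequence_degap"
                    else "fragments must come from a common alignment"
                )
            )
    if deletion == "complete":
        keep = [
            i
            for i in range(length)
            if all(s[i] in STANDARD_AA for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
        if not keep:
            raise DistanceError("complete deletion removed every site")

    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p = p_distance(seqs[i], seqs[j])
                d = poisson_distance(p)
            except DistanceError as exc:
                raise DistanceError(
                    f"domain {name!r}, pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from None
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, name=name, deletion=deletion)


# ---------------------------------------------------------------------------
# divergence-time matrices
# ---------------------------------------------------------------------------

def time_matrix_from_newick(source: str | Path) -> DistanceMatrix:
    """Pairwise divergence matrix from a newick tree: entry (i, j) is the sum
    of branch lengths on the path between leaves i and j."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise DistanceError(f"negative branch length {edge.length} in tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = tuple(t.label for t in taxa)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, name="time")


def time_matrix_from_table(path: str | Path) -> DistanceMatrix:
    """Pairwise divergence matrix from a TSV of (id1, id2, time) rows.

    The table is symmetrized; every unordered pair must be present at least
    once (conflicting duplicate entries are an error)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise DistanceError(f"{path}: expected columns id1, id2, time")
    id1, id2, t = df.columns[:3]
    ids = tuple(sorted(set(df[id1]) | set(df[id2])))
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    for _, row in df.iterrows():
        i, j = index[row[id1]], index[row[id2]]
        val = float(row[t])
        for a, b in ((i, j), (j, i)):
            if not np.isnan(values[a, b]) and values[a, b] != val:
                raise DistanceError(
                    f"{path}: conflicting times for pair ({ids[i]}, {ids[j]})"
                )
            values[a, b] = val
    missing = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(values[i, j])
    ]
    if missing:
        raise DistanceError(f"{path}: missing pairs {missing[:5]}")
    return DistanceMatrix(ids, values, name="time")


def time_matrix(source: str | Path) -> DistanceMatrix:
    """Dispatch on input kind: newick text, newick file, or pairwise TSV."""
    if isinstance(source, str) and "(" in source:
        return time_matrix_from_newick(source)
    path = Path(source)
    if path.suffix.lower() in (".nwk", ".newick", ".tree", ".tre"):
        return time_matrix_from_newick(path)
    head = path.read_text().lstrip()
    if head.startswith("("):
        return time_matrix_from_newick(path)
    return time_matrix_from_table(path)


def is_ultrametric(m: DistanceMatrix, tol: float = 1e-9) -> bool:
    """Three-point condition: for every triple, the largest of the three
    pairwise values is attained at least twice (within ``tol``)."""
    n = len(m.ids)
    v = m.values
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                trio = sorted((v[i, j], v[i, k], v[j, k]))
                if trio[2] - trio[1] > tol:
                    return False
    return True
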