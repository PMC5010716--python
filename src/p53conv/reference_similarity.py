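"""Reference-species similarity: phylogeny-expected vs domain-observed
close/distant composition.

The design: pick one reference species from the putatively convergent
group (the study organism — e.g. a hypoxia-tolerant subterranean rodent),
and ask whether, for a given protein domain, more convergent-group (HT)
species rank among the reference's sequence-nearest neighbours than
phylogeny predicts.

Two 2x2 tables with identical margins are built. The *expected* table
counts HT/HS species that are phylogenetically close to the reference
(by clade membership, e.g. Rodentia/Lagomorpha, or by a divergence-time
threshold). The *observed* table keeps the same number of "close" slots
but fills them with the species nearest to the reference by *domain
distance*. Because the expected composition is itself skewed, the Fisher
test on the observed table uses a noncentral null with odds ratio

    null_or = (H_close / H_dist) / (S_close / S_dist)

computed from the expected table, so the test asks whether the observed
composition deviates from the phylogenetic expectation rather than from a
uniform one. A jackknife-style resampling (repeated subsampling without
replacement at fixed sizes, averaging p) probes the stability of the
result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import SpeciesRecord
from .distances import DistanceMatrix
from .pattern_analysis import fisher_2x2


class ReferenceError(ValueError):
    """Raised for invalid close/distant table construction."""


@dataclass(frozen=True)
class CloseDistantTables:
    """Expected (phylogeny) and observed (domain distance) 2x2 tables.

    Rows: HT / HS; columns: close / distant. Both tables share row totals
    (group sizes) and column totals (number of "close" slots); ``null_or``
    is the odds ratio of the expected table (with a Haldane-Anscombe +0.5
    on all four cells, applied only to the odds-ratio computation, when a
    zero cell would make it degenerate). ``tied_boundary`` flags a distance
    tie across the close/distant cut, resolved lexicographically.
    """

    expected: np.ndarray
    observed: np.ndarray
    null_or: float
    tied_boundary: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.expected, dtype=int)
        o = np.asarray(self.observed, dtype=int)
        object.__setattr__(self, "expected", e)
        object.__setattr__(self, "observed", o)
        if e.shape != (2, 2) or o.shape != (2, 2):
            raise ReferenceError("expected and observed tables must be 2x2")
        if np.any(e < 0) or np.any(o < 0):
            raise ReferenceError("table counts must be non-negative")
        if not np.array_equal(e.sum(axis=1), o.sum(axis=1)):
            raise ReferenceError("row totals (group sizes) differ between tables")
        if not np.array_equal(e.sum(axis=0), o.sum(axis=0)):
            raise ReferenceError("column totals (close counts) differ between tables")
        if self.null_or <= 0:
            raise ReferenceError(f"null odds ratio must be positive, got {self.null_or}")


def _expected_odds_ratio(expected: np.ndarray) -> float:
    """(H_close/H_dist)/(S_close/S_dist); Haldane-Anscombe +0.5 on all
    cells iff any cell is zero (never applied to the counts themselves)."""
    e = expected.astype(float)
    if np.any(e == 0):
        e = e + 0.5
    return float((e[0, 0] / e[0, 1]) / (e[1, 0] / e[1, 1]))


def expected_table(
    species: Sequence[SpeciesRecord],
    ref: str,
    close_clades: set[str] | None = None,
    time_threshold: float | None = None,
    times: DistanceMatrix | None = None,
    ht_group: str = "hypoxic",
    hs_groups: Sequence[str] = ("metabolic", "non_stress"),
) -> tuple[np.ndarray, set[str]]:
    """Phylogeny-expected 2x2 table and the set of "close" species.

    ``close_clades`` classifies species as close by clade tag;
    alternatively ``time_threshold`` (with a divergence-time matrix)
    classifies as close every species nearer to the reference than the
    threshold. The reference itself is excluded from all counts.
    """
    if (close_clades is None) == (time_threshold is None):
        raise ReferenceError("give exactly one of close_clades or time_threshold")
    if time_threshold is not None and times is None:
        raise ReferenceError("time_threshold requires a divergence-time matrix")

    ht = [r for r in species if r.group == ht_group and r.species_id != ref]
    hs = [r for r in species if r.group in hs_groups and r.species_id != ref]
    if any(r.species_id == ref for r in species if r.group in (ht_group, *hs_groups)):
        warnings.warn(
            f"reference {ref!r} listed in a tested group; excluded from counts",
            stacklevel=2,
        )
    if not ht or not hs:
        raise ReferenceError(
            f"empty group: HT={len(ht)} HS={len(hs)} (ref {ref!r} excluded)"
        )

    def is_close(r: SpeciesRecord) -> bool:
        if close_clades is not None:
            return r.clade in close_clades
        return times.get(ref, r.species_id) < time_threshold

    close_ids = {r.species_id for r in (*ht, *hs) if is_close(r)}
    table = np.array(
        [
            [sum(r.species_id in close_ids for r in ht),
             sum(r.species_id not in close_ids for r in ht)],
            [sum(r.species_id in close_ids for r in hs),
             sum(r.species_id not in close_ids for r in hs)],
        ]
    )
    return table, close_ids


def observed_table(
    matrix: DistanceMatrix,
    ref: str,
    species: Sequence[SpeciesRecord],
    n_close: int,
    ht_group: str = "hypoxic",
    hs_groups: Sequence[str] = ("metabolic", "non_stress"),
) -> tuple[np.ndarray, bool]:
    """Domain-distance 2x2 table: the ``n_close`` species nearest to the
    reference (by the domain distance matrix) fill the "close" column.

    Distance ties across the boundary are broken by species_id
    lexicographic order; the returned flag reports whether such a tie
    occurred."""
    pool = [
        r for r in species
        if r.species_id != ref and r.group in (ht_group, *hs_groups)
    ]
    if n_close >= len(pool):
        raise ReferenceError(
            f"n_close = {n_close} must be smaller than the {len(pool)} "
            "non-reference species"
        )
    if n_close < 1:
        raise ReferenceError("n_close must be at least 1")
    dist = {r.species_id: matrix.get(ref, r.species_id) for r in pool}
    ranked = sorted(dist, key=lambda s: (dist[s], s))
    close_ids = set(ranked[:n_close])
    tied = dist[ranked[n_close - 1]] == dist[ranked[n_close]]
    ht = [r for r in pool if r.group == ht_group]
    hs = [r for r in pool if r.group in hs_groups]
    table = np.array(
        [
            [sum(r.species_id in close_ids for r in ht),
             sum(r.species_id not in close_ids for r in ht)],
            [sum(r.species_id in close_ids for r in hs),
             sum(r.species_id not in close_ids for r in hs)],
        ]
    )
    return table, tied


def close_distant_tables(
    species: Sequence[SpeciesRecord],
    matrix: DistanceMatrix,
    ref: str,
    close_clades: set[str] | None = None,
    time_threshold: float | None = None,
    times: DistanceMatrix | None = None,
    ht_group: str = "hypoxic",
    hs_groups: Sequence[str] = ("metabolic", "non_stress"),
) -> CloseDistantTables:
    """Build the paired expected/observed tables for one domain matrix."""
    exp, close_ids = expected_table(
        species, ref,
        close_clades=close_clades, time_threshold=time_threshold, times=times,
        ht_group=ht_group, hs_groups=hs_groups,
    )
    n_close = int(exp[:, 0].sum())
    if n_close == 0:
        raise ReferenceError("no species is phylogenetically close to the reference")
    obs, tied = observed_table(
        matrix, ref, species, n_close, ht_group=ht_group, hs_groups=hs_groups
    )
    return CloseDistantTables(
        expected=exp, observed=obs,
        null_or=_expected_odds_ratio(exp), tied_boundary=tied,
    )


def adjusted_fisher(
    tables: CloseDistantTables, alternative: str = "two_sided"
) -> float:
    """Fisher's exact test of the observed table against the noncentral
    null whose odds ratio comes from the expected (phylogenetic) table.

    ``greater`` tests for an excess of HT species among the sequence-close
    set beyond the phylogenetic expectation."""
    return fisher_2x2(
        tables.observed, alternative=alternative, null_or=tables.null_or
    )


def jackknife_mean_p(
    species: Sequence[SpeciesRecord],
    matrix: DistanceMatrix,
    ref: str,
    sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    alternative: str = "two_sided",
    close_clades: set[str] | None = None,
    time_threshold: float | None = None,
    times: DistanceMatrix | None = None,
    ht_group: str = "hypoxic",
    hs_groups: Sequence[str] = ("metabolic", "non_stress"),
) -> dict[int, dict[str, float]]:
    """Repeat the adjusted Fisher test on random subsamples and average p.

    For each requested size, ``reps`` subsamples of the non-reference
    species are drawn without replacement (the reference is always
    retained), both tables are rebuilt, and the mean p-value is reported
    together with the number of replicates skipped because a subsample
    emptied a group or the close set. Seeded and reproducible.
    """
    if reps < 1:
        raise ReferenceError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pool = [r for r in species if r.species_id != ref]
    ref_records = [r for r in species if r.species_id == ref]
    out: dict[int, dict[str, float]] = {}
    for size in sizes:
        if not 1 <= size <= len(pool):
            raise ReferenceError(
                f"subsample size {size} outside 1..{len(pool)} non-reference species"
            )
        ps = []
        skipped = 0
        for _ in range(reps):
            idx = rng.choice(len(pool), size=size, replace=False)
            sub = [pool[i] for i in sorted(idx)] + ref_records
            try:
                tables = close_distant_tables(
                    sub, matrix, ref,
                    close_clades=close_clades,
                    time_threshold=time_threshold, times=times,
                    ht_group=ht_group, hs_groups=hs_groups,
                )
                ps.append(adjusted_fisher(tables, alternative=alternative))
            except ReferenceError:
                skipped += 1
        if skipped:
            warnings.warn(
                f"size {size}: {skipped}/{reps} replicates skipped "
                "(empty group or empty close set)",
                stacklevel=2,
            )
        out[size] = {
            "mean_p": float(np.mean(ps)) if ps else float("nan"),
            "n_used": float(len(ps)),
            "n_skipped": float(skipped),
        }
    return out
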