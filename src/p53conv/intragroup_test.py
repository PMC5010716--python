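"""Intra-group similarity U test with a Monte-Carlo null for dependent
pairwise distances.

The question this module answers: for a given protein domain, are the
pairwise distances *within* one group of species (e.g. hypoxia-tolerant,
HT) systematically smaller than those within a matched group (e.g.
hypoxia-sensitive, HS)? Each group of k species contributes the vector
S_G of all n = k(k-1)/2 intra-group pairwise distances, and the test
statistic is the Mann-Whitney-type count

    U = #{ (a, b) : S_1[a] > S_2[b] },   EU = n1 * n2 / 2 under H0.

The n distances in each vector are *not* independent — they derive from k
points in a metric space, so d_ij, d_jk constrain d_ik — which invalidates
the standard Mann-Whitney null. Three null distributions are offered:

* exact: the classical no-ties Mann-Whitney null (count recursion), valid
  only under independence; reported for reference.
* normal: the large-sample normal approximation with tie correction.
* Monte-Carlo geometric null: in each of N runs, place k1 + k2 i.i.d.
  uniform points in the unit hypercube [0, 1]^dim, compute the two
  intra-group Euclidean distance vectors, and record U. This null
  preserves exactly the metric dependencies among the pairwise distances.

One-sided "lower" p-values test the alternative that group 1's intra-group
distances are smaller (convergence within group 1). A Benjamini-Hochberg
FDR column is added across domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_io import DomainFragmentSet, SpeciesRecord
from .distances import DistanceMatrix, distance_matrix


class UTestError(ValueError):
    """Raised for invalid test inputs."""


@dataclass(frozen=True)
class GroupDistanceVector:
    """All k(k-1)/2 intra-group pairwise distances for one group."""

    group: str
    members: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        k = len(self.members)
        if v.ndim != 1 or len(v) != k * (k - 1) // 2:
            raise UTestError(
                f"group {self.group!r}: {len(v)} distances for {k} members; "
                f"expected k(k-1)/2 = {k * (k - 1) // 2}"
            )
        if np.any(v < 0):
            raise UTestError(f"group {self.group!r}: negative distances")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MCNullSample:
    """Seeded Monte-Carlo sample of U under the geometric null."""

    k1: int
    k2: int
    n_runs: int
    dim: int
    seed: int
    tie_rule: str
    values: np.ndarray

    @property
    def n1(self) -> int:
        return self.k1 * (self.k1 - 1) // 2

    @property
    def n2(self) -> int:
        return self.k2 * (self.k2 - 1) // 2

    @property
    def eu(self) -> float:
        return self.n1 * self.n2 / 2


@dataclass(frozen=True)
class UTestResult:
    """Test summary for one domain (or for the divergence-time control)."""

    domain: str
    u_obs: float
    n1: int
    n2: int
    p_exact: float
    p_normal: float
    p_mc: float
    n_mc: int
    mc_dim: int
    seed: int
    tie_rule: str

    @property
    def eu(self) -> float:
        return self.n1 * self.n2 / 2


@dataclass(frozen=True)
class UTestConfig:
    """Settings shared across domains in one analysis run.

    ``tie_rule``: "strict" counts only S1 > S2 pairs (the definition used
    for the headline results); "half" adds 0.5 per tie, restoring the
    U1 + U2 = n1*n2 identity when distances tie.
    ``mc_dim``: dimension of the unit hypercube of the geometric null; the
    null's U variance is only weakly sensitive to it (see the methods note).
    ``mc_pseudocount``: report (r + 1)/(N + 1) instead of r/N, so Monte-Carlo
    p-values are never exactly zero.
    """

    tie_rule: str = "strict"
    tail: str = "lower"
    mc_n: int = 100_000
    mc_dim: int = 2
    seed: int = 0
    deletion: str = "complete"
    mc_pseudocount: bool = False


def intra_group_distances(
    m: DistanceMatrix, members: Sequence[str], group: str = ""
) -> GroupDistanceVector:
    """Extract the vector of all within-group pairwise distances.

    Members are sorted lexicographically and pairs enumerated in
    lexicographic (i, j) order, so the vector layout is deterministic.
    """
    members = sorted(members)
    if len(members) < 2:
        raise UTestError(f"group {group!r} needs at least 2 members")
    if len(set(members)) != len(members):
        raise UTestError(f"group {group!r} has duplicate members")
    for s in members:
        if s not in m.ids:
            raise UTestError(f"species {s!r} absent from matrix {m.name!r}")
    values = [
        m.get(a, b)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    ]
    return GroupDistanceVector(group=group, members=tuple(members), values=np.array(values))


def u_statistic(
    s1: GroupDistanceVector | Sequence[float],
    s2: GroupDistanceVector | Sequence[float],
    tie_rule: str = "strict",
) -> float:
    """Count of cross pairs with s1 > s2; ties add 0.5 under "half"."""
    a = np.asarray(s1.values if isinstance(s1, GroupDistanceVector) else s1, dtype=float)
    b = np.asarray(s2.values if isinstance(s2, GroupDistanceVector) else s2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UTestError("empty distance vector")
    if tie_rule not in ("strict", "half"):
        raise UTestError(f"unknown tie rule {tie_rule!r}")
    gt = np.sum(a[:, None] > b[None, :])
    if tie_rule == "strict":
        return float(gt)
    ties = np.sum(a[:, None] == b[None, :])
    return float(gt) + 0.5 * float(ties)


# ---------------------------------------------------------------------------
# exact null (no ties)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements with each U value, via the recursion
    N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)."""
    if n1 == 0 or n2 == 0:
        return (1,)
    left = _u_counts(n1 - 1, n2)  # indices shifted by n2
    right = _u_counts(n1, n2 - 1)
    total = n1 * n2
    out = [0] * (total + 1)
    for u, c in enumerate(left):
        out[u + n2] += c
    for u, c in enumerate(right):
        out[u] += c
    return tuple(out)


def exact_mw_pvalue(u_obs: float, n1: int, n2: int, tail: str = "lower") -> float:
    """Exact Mann-Whitney p-value under the no-ties null.

    ``lower`` is P(U <= u_obs), the tail for the alternative that group 1's
    values are systematically smaller.
    """
    if n1 < 1 or n2 < 1:
        raise UTestError("need n1, n2 >= 1")
    if u_obs != int(u_obs):
        raise UTestError(
            f"non-integer U = {u_obs} (ties counted as half); the exact "
            "no-ties null is undefined — use the normal approximation"
        )
    u = int(u_obs)
    total = n1 * n2
    if not 0 <= u <= total:
        raise UTestError(f"U = {u} outside [0, {total}]")
    counts = _u_counts(n1, n2)
    denom = comb(n1 + n2, n1)
    lower = sum(counts[: u + 1]) / denom
    upper = sum(counts[u:]) / denom
    if tail == "lower":
        return lower
    if tail == "upper":
        return upper
    if tail == "two":
        return min(1.0, 2.0 * min(lower, upper))
    raise UTestError(f"unknown tail {tail!r}")


def normal_mw_pvalue(
    u_obs: float,
    n1: int,
    n2: int,
    tail: str = "lower",
    continuity: bool = True,
    tie_counts: Sequence[int] | None = None,
) -> float:
    """Normal-approximation Mann-Whitney p-value, optionally tie-corrected.

    ``tie_counts`` are the sizes of tie groups in the pooled sample of
    n1 + n2 values; the usual variance correction
    sigma^2 = n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N(N-1))] is applied.
    """
    if n1 < 1 or n2 < 1:
        raise UTestError("need n1, n2 >= 1")
    big_n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = 0.0
    if tie_counts is not None:
        tie_term = sum(t**3 - t for t in tie_counts) / (big_n * (big_n - 1))
    var = n1 * n2 / 12 * ((big_n + 1) - tie_term)
    if var <= 0:
        raise UTestError("zero variance: all pooled values are tied")
    sd = sqrt(var)
    cc = 0.5 if continuity else 0.0
    if tail == "lower":
        return float(norm.cdf((u_obs + cc - mu) / sd))
    if tail == "upper":
        return float(norm.sf((u_obs - cc - mu) / sd))
    if tail == "two":
        z = (abs(u_obs - mu) - cc) / sd
        return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    raise UTestError(f"unknown tail {tail!r}")


# ---------------------------------------------------------------------------
# Monte-Carlo geometric null
# ---------------------------------------------------------------------------

def _intra_distances(points: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Euclidean intra-group distances for points[:, lo:hi, :] of shape
    (runs, k, dim) -> (runs, k(k-1)/2)."""
    group = points[:, lo:hi, :]
    k = hi - lo
    ii, jj = np.triu_indices(k, 1)
    diff = group[:, ii, :] - group[:, jj, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def mc_null(
    k1: int,
    k2: int,
    n_runs: int,
    dim: int = 2,
    seed: int = 0,
    tie_rule: str = "strict",
    batch: int = 20_000,
) -> MCNullSample:
    """Sample the null distribution of U from random point configurations.

    Each run places k1 + k2 i.i.d. uniform points in [0, 1]^dim, splits them
    into the first k1 and last k2, computes the two intra-group Euclidean
    distance vectors and records U. Because the distances of each group come
    from actual points in a metric space, the sample reproduces the
    triangle-inequality dependencies that the standard Mann-Whitney null
    ignores. Bit-reproducible for a given seed.
    """
    if k1 < 2 or k2 < 2:
        raise UTestError("need k1, k2 >= 2")
    if n_runs < 1 or dim < 1:
        raise UTestError("need n_runs >= 1 and dim >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    done = 0
    while done < n_runs:
        m = min(batch, n_runs - done)
        pts = rng.random((m, k1 + k2, dim))
        d1 = _intra_distances(pts, 0, k1)
        d2 = _intra_distances(pts, k1, k1 + k2)
        gt = np.sum(d1[:, :, None] > d2[:, None, :], axis=(1, 2)).astype(float)
        if tie_rule == "half":  # ties have probability zero here, kept for form
            gt += 0.5 * np.sum(d1[:, :, None] == d2[:, None, :], axis=(1, 2))
        chunks.append(gt)
        done += m
    values = np.concatenate(chunks)
    return MCNullSample(
        k1=k1, k2=k2, n_runs=n_runs, dim=dim, seed=seed,
        tie_rule=tie_rule, values=values,
    )


def mc_pvalue(
    u_obs: float,
    sample: MCNullSample,
    tail: str = "lower",
    pseudocount: bool = False,
) -> float:
    """Monte-Carlo p-value as the proportion of simulated runs at least as
    extreme as the observation.

    ``lower``: #{U_sim <= U_obs} / N, for the alternative that group 1 is
    more internally similar. ``two_symmetric``: #{|U_sim - EU| >= |U_obs -
    EU|} / N. With ``pseudocount``, (r + 1)/(N + 1) is reported instead.
    """
    v = sample.values
    n = len(v)
    if n == 0:
        raise UTestError("empty Monte-Carlo sample")
    if tail == "lower":
        r = int(np.sum(v <= u_obs))
    elif tail == "two_symmetric":
        eu = sample.eu
        r = int(np.sum(np.abs(v - eu) >= abs(u_obs - eu)))
    else:
        raise UTestError(f"unknown tail {tail!r}")
    if pseudocount:
        return (r + 1) / (n + 1)
    return r / n


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise UTestError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_domain_tests(
    inputs: Mapping[str, DomainFragmentSet | DistanceMatrix],
    species: Sequence[SpeciesRecord],
    group1: str,
    group2: str,
    config: UTestConfig = UTestConfig(),
) -> pd.DataFrame:
    """Run the intra-group U test for every domain and add FDR columns.

    ``inputs`` maps a domain name to either a fragment set (a Poisson
    distance matrix is built) or a ready distance matrix (e.g. the
    divergence-time control). Group 1 is the putatively convergent group;
    the reported one-sided p-values are for *smaller* group-1 intra-group
    distances. The Monte-Carlo null is sampled once (it depends only on the
    group sizes) and shared across domains.
    """
    members1 = sorted(r.species_id for r in species if r.group == group1)
    members2 = sorted(r.species_id for r in species if r.group == group2)
    if len(members1) < 2 or len(members2) < 2:
        raise UTestError(
            f"groups {group1!r} ({len(members1)}) and {group2!r} "
            f"({len(members2)}) both need k >= 2"
        )

    null = mc_null(
        len(members1), len(members2), config.mc_n, config.mc_dim,
        seed=config.seed, tie_rule=config.tie_rule,
    )
    mc_tail = "lower" if config.tail == "lower" else "two_symmetric"

    results: list[UTestResult] = []
    for name, item in inputs.items():
        if isinstance(item, DistanceMatrix):
            matrix = item
        else:
            for s in members1 + members2:
                if s not in item.fragments:
                    raise UTestError(
                        f"domain {name!r}: species {s!r} missing from fragments"
                    )
            matrix = distance_matrix(item, deletion=config.deletion)
        s1 = intra_group_distances(matrix, members1, group=group1)
        s2 = intra_group_distances(matrix, members2, group=group2)
        u = u_statistic(s1, s2, tie_rule=config.tie_rule)
        try:
            p_exact = exact_mw_pvalue(u, s1.n, s2.n, tail=config.tail)
        except UTestError:
            p_exact = float("nan")  # half-integer U under the half-tie rule
        pooled = np.concatenate([s1.values, s2.values])
        _, tie_sizes = np.unique(pooled, return_counts=True)
        try:
            p_normal = normal_mw_pvalue(
                u, s1.n, s2.n, tail=config.tail,
                tie_counts=[int(t) for t in tie_sizes if t > 1],
            )
        except UTestError:
            p_normal = float("nan")  # all pooled distances tied
        p_mc = mc_pvalue(u, null, tail=mc_tail, pseudocount=config.mc_pseudocount)
        results.append(
            UTestResult(
                domain=name, u_obs=u, n1=s1.n, n2=s2.n,
                p_exact=p_exact, p_normal=p_normal, p_mc=p_mc,
                n_mc=config.mc_n, mc_dim=config.mc_dim,
                seed=config.seed, tie_rule=config.tie_rule,
            )
        )

    df = pd.DataFrame(
        {
            "domain": [r.domain for r in results],
            "U_obs": [r.u_obs for r in results],
            "EU": [r.eu for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "p_exact": [r.p_exact for r in results],
            "p_normal": [r.p_normal for r in results],
            "p_mc": [r.p_mc for r in results],
        }
    )
    # FDR across domains, excluding the divergence-time control if present
    for col, adj in (("p_exact", "q_exact"), ("p_mc", "q_mc")):
        mask = df["domain"].str.lower() != "time"
        p = df.loc[mask, col]
        usable = p.notna()
        df[adj] = np.nan
        if usable.any():
            df.loc[p.index[usable], adj] = bh_fdr(p[usable].tolist())
    return df
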