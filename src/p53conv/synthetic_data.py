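"""Self-contained synthetic datasets with implanted convergent motifs.

The generator emulates the study design the statistics in this package are
built for: a *balanced pair* phylogeny — each putatively convergent
(hypoxia-tolerant, HT) species matched with a hypoxia-sensitive (HS)
sister, every pair with its own last common ancestor — protein evolution
under a 20-state equal-rates substitution model (the protein analogue of
Jukes-Cantor, the model under which the Poisson-corrected distance is the
natural estimator), and convergent evolution injected as a gapped motif
overwritten into a fixed window of a designated domain in each HT taxon
independently with probability pi.

Time is measured in units of 100 million years. The default tree is a
caterpillar of cherries whose joins are compressed between 0.9 and 0.99 —
a rapid radiation, the realistic picture for placental interordinal
splits — with short terminal cherries (depth 0.1). Compressing the joins
keeps the baseline cross-pair divergence homogeneous, so the implanted
convergent signal, not depth heterogeneity, dominates the intra-group
distance contrast. The default rate of 0.5 substitutions/site per unit
time puts cross-pair p-distances near 0.6, the regime of rapidly evolving
disordered protein regions over deep mammalian comparisons (conserved
domains evolve far slower; for testing the statistics only the distance
scale matters).

Implantation overwrites rather than mutates, so the carrier set is exact
ground truth and the effect size is tuned by pi and motif length alone.
The default implant is the fully specified pentapeptide DLLAT — a
realization of the [DE]LLX[ST]-style signature: a convergent event fixes
identical residues, while wildcards and residue classes belong to the
*scanning* grammar that later recognizes it. Sequences are gap-free:
indel realism contributes nothing to any statistic tested here.

At the default divergence a deep pair differing at all sites of a 21-site
domain (undefined Poisson distance) has probability ~1e-5; the simulation
-study helpers below record and skip such replicates rather than abort,
while real analyses keep the hard error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .core_io import (
    Alignment,
    DomainSpec,
    SpeciesRecord,
    read_alignment,
    read_species_table,
    write_alignment,
    write_species_table,
)
from .pattern_analysis import (
    Any_,
    Fixed,
    MotifPattern,
    ResidueClass,
    parse_pattern,
    render_pattern,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass(frozen=True)
class ImplantSpec:
    """Convergent-motif implantation settings.

    ``window_start`` is 1-based within the target domain; each HT taxon
    independently receives the motif with probability ``prob`` (pi).
    Species named in ``always`` are implanted unconditionally — used by the
    reference-similarity studies, where the reference species defines the
    motif and therefore carries it by construction."""

    motif: MotifPattern
    domain: str
    window_start: int = 3
    prob: float = 1.0
    always: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.motif, str):
            object.__setattr__(self, "motif", parse_pattern(self.motif))
        if not 0.0 <= self.prob <= 1.0:
            raise SimulationError(f"pi must lie in [0, 1], got {self.prob}")
        if self.window_start < 1:
            raise SimulationError("window_start is 1-based and must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the balanced design the statistics target: 5 HT/HS
    sister pairs, two 21-site domains (one implanted, one control), and
    full implantation (pi = 1) of the pentapeptide DLLAT.
    """

    n_pairs: int = 5
    domain_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"TAD2": 21, "CTRL": 21}
    )
    rate: float = 0.5
    cherry_depth: float = 0.1
    backbone_depths: tuple[float, ...] | None = None
    implant: ImplantSpec | None = field(
        default_factory=lambda: ImplantSpec(
            motif=parse_pattern("DLLAT"), domain="TAD2", window_start=3, prob=1.0
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise SimulationError("need at least 2 sister pairs")
        if self.rate < 0:
            raise SimulationError("rate must be non-negative")
        if self.implant is not None:
            dom = self.implant.domain
            if dom not in self.domain_lengths:
                raise SimulationError(f"implant domain {dom!r} not simulated")
            end = self.implant.window_start + len(self.implant.motif.tokens) - 1
            if end > self.domain_lengths[dom]:
                raise SimulationError(
                    f"implant window ends at {end} but domain {dom!r} has "
                    f"{self.domain_lengths[dom]} sites"
                )


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset plus its ground truth.

    ``truth`` maps carrier species ids to the realized motif string; the
    window and motif are recorded alongside for verification against
    motif scans of the emitted sequences."""

    alignment: Alignment
    species: tuple[SpeciesRecord, ...]
    tree: str
    domains: Mapping[str, DomainSpec]
    truth: dict

    def fragments(self) -> dict[str, dict[str, str]]:
        """Per-domain fragment dicts (sequences are gap-free, so domain
        extraction is plain slicing)."""
        out = {}
        for name, dom in self.domains.items():
            out[name] = {
                sid: seq[dom.ref_start - 1 : dom.ref_end]
                for sid, seq in self.alignment
            }
        return out


def default_backbone_depths(n_pairs: int, cherry_depth: float = 0.1) -> tuple[float, ...]:
    """Caterpillar join times compressed between 0.9 and 0.99 time units
    (a radiation); requires cherry_depth < 0.9."""
    if n_pairs == 2:
        return (0.9,)
    return tuple(0.9 + 0.09 * i / (n_pairs - 2) for i in range(n_pairs - 1))


def make_balanced_tree(
    n_pairs: int,
    cherry_depth: float = 0.1,
    backbone_depths: Sequence[float] | None = None,
    seed: int | None = None,
) -> str:
    """Ultrametric caterpillar of HT/HS cherries as newick text.

    Pair i contributes leaves ``pair{i}_HT`` and ``pair{i}_HS`` joined at
    ``cherry_depth``; successive pairs attach at the (strictly increasing)
    ``backbone_depths``. Deterministic — the ``seed`` argument is accepted
    for interface symmetry with the stochastic generators but unused.
    """
    if n_pairs < 2:
        raise SimulationError("need at least 2 pairs")
    if cherry_depth <= 0:
        raise SimulationError("cherry_depth must be positive")
    if backbone_depths is None:
        backbone_depths = default_backbone_depths(n_pairs, cherry_depth)
    backbone_depths = tuple(float(t) for t in backbone_depths)
    if len(backbone_depths) != n_pairs - 1:
        raise SimulationError(
            f"need {n_pairs - 1} backbone depths for {n_pairs} pairs, "
            f"got {len(backbone_depths)}"
        )
    prev = cherry_depth
    for t in backbone_depths:
        if t <= prev:
            raise SimulationError(
                "backbone depths must be strictly increasing and exceed cherry_depth"
            )
        prev = t

    def cherry(i: int) -> str:
        return (
            f"(pair{i:02d}_HT:{cherry_depth:.10g},pair{i:02d}_HS:{cherry_depth:.10g})"
        )

    subtree = cherry(1)
    height = cherry_depth
    for i, t in enumerate(backbone_depths, start=2):
        subtree = f"({subtree}:{t - height:.10g},{cherry(i)}:{t - cherry_depth:.10g})"
        height = t
    return subtree + ";"


def species_table_for_tree(n_pairs: int) -> tuple[SpeciesRecord, ...]:
    """HT leaves labeled ``hypoxic``, HS leaves ``non_stress``; each pair
    carries its own clade tag."""
    records = []
    for i in range(1, n_pairs + 1):
        clade = f"clade{i:02d}"
        records.append(SpeciesRecord(f"pair{i:02d}_HT", "hypoxic", clade=clade))
        records.append(SpeciesRecord(f"pair{i:02d}_HS", "non_stress", clade=clade))
    return tuple(records)


def domain_spec_map(lengths: Mapping[str, int]) -> dict[str, DomainSpec]:
    """Lay the simulated domains end to end on the concatenated sequence."""
    out = {}
    pos = 1
    for name, length in lengths.items():
        if length < 1:
            raise SimulationError(f"domain {name!r} must have >= 1 site")
        out[name] = DomainSpec(name, pos, pos + length - 1)
        pos += length
    return out


def simulate_sequences(
    tree: str,
    lengths: Mapping[str, int],
    rate: float,
    seed: int = 0,
) -> Alignment:
    """Evolve gap-free sequences down the tree under the 20-state
    equal-rates model.

    Root sites are i.i.d. uniform over the 20 amino acids; along a branch
    of length b each site substitutes with probability 1 - exp(-rate * b),
    the replacement drawn uniformly from the other 19 residues; sites are
    independent. Leaf rows are emitted in tree leaf order.
    """
    if rate < 0:
        raise SimulationError("rate must be non-negative")
    total = sum(lengths.values())
    rng = np.random.default_rng(seed)
    t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    seqs: dict[int, np.ndarray] = {}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            state = rng.integers(0, 20, size=total)
        else:
            parent = seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            p_sub = 1.0 - np.exp(-rate * b)
            hit = rng.random(total) < p_sub
            state = parent.copy()
            # +1..+19 mod 20 is uniform over the 19 other residues
            state[hit] = (state[hit] + rng.integers(1, 20, size=int(hit.sum()))) % 20
        seqs[id(node)] = state
        if node.is_leaf():
            leaves.append((node.taxon.label, state))
    rows = [
        (label, "".join(AA_ALPHABET[s] for s in state)) for label, state in leaves
    ]
    return Alignment(rows)


def implant_motif(
    aln: Alignment,
    species: Sequence[SpeciesRecord],
    implant: ImplantSpec,
    domains: Mapping[str, DomainSpec],
    seed: int = 0,
    tree: str = "",
) -> SimulatedDataset:
    """Overwrite the implant window with a motif realization in each HT
    taxon independently with probability pi; HS taxa are untouched.

    Fixed tokens are written literally, class tokens sampled uniformly
    from the class per carrier, wildcard positions left unchanged. The
    carrier set and realized windows are recorded as ground truth.
    """
    dom = domains.get(implant.domain)
    if dom is None:
        raise SimulationError(f"implant domain {implant.domain!r} unknown")
    tokens = implant.motif.tokens
    start = dom.ref_start + implant.window_start - 1  # absolute, 1-based
    end = start + len(tokens) - 1
    if end > dom.ref_end:
        raise SimulationError(
            f"motif of length {len(tokens)} does not fit the window at "
            f"{implant.window_start} of domain {implant.domain!r}"
        )
    rng = np.random.default_rng(seed)
    ht_ids = [r.species_id for r in species if r.group == "hypoxic"]
    carriers: dict[str, str] = {}
    rows = []
    for sid, seq in aln:
        if sid in implant.always or (
            sid in ht_ids and rng.random() < implant.prob
        ):
            window = list(seq[start - 1 : end])
            for off, tok in enumerate(tokens):
                if isinstance(tok, Fixed):
                    window[off] = tok.residue
                elif isinstance(tok, ResidueClass):
                    window[off] = rng.choice(sorted(tok.residues))
                # Any_: leave the evolved residue
            realized = "".join(window)
            seq = seq[: start - 1] + realized + seq[end:]
            carriers[sid] = realized
        rows.append((sid, seq))
    truth = {
        "motif": render_pattern(implant.motif),
        "domain": implant.domain,
        "window": [start, end],
        "pi": implant.prob,
        "carriers": carriers,
    }
    return SimulatedDataset(
        alignment=Alignment(rows),
        species=tuple(species),
        tree=tree,
        domains=dict(domains),
        truth=truth,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset (tree, sequences, metadata, implantation)
    from one seed."""
    rng = np.random.default_rng(config.seed)
    seq_seed, implant_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    tree = make_balanced_tree(
        config.n_pairs, config.cherry_depth, config.backbone_depths
    )
    aln = simulate_sequences(tree, config.domain_lengths, config.rate, seed=seq_seed)
    species = species_table_for_tree(config.n_pairs)
    domains = domain_spec_map(config.domain_lengths)
    if config.implant is None:
        return SimulatedDataset(
            alignment=aln, species=species, tree=tree, domains=domains,
            truth={"motif": None, "carriers": {}},
        )
    return implant_motif(
        aln, species, config.implant, domains, seed=implant_seed, tree=tree
    )


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------

def replicate_pvalues(
    n_reps: int,
    null_sample,
    pi: float = 1.0,
    domain: str = "TAD2",
    seed: int = 0,
    config: SimulationConfig | None = None,
    tie_rule: str = "strict",
    tail: str = "lower",
) -> dict:
    """Monte-Carlo p-values of the intra-group U test over seeded replicates.

    Replicate i simulates a dataset from ``config`` reseeded with
    ``seed + i`` and implantation probability ``pi`` (pi = 0 is the null),
    computes the Poisson distance matrix of ``domain``, the U statistic
    between the hypoxic and non_stress intra-group distance vectors, and
    its p-value against ``null_sample`` (an
    :class:`~p53conv.intragroup_test.MCNullSample` for the matching group
    sizes). Replicates whose distance matrix is undefined because a deep
    pair saturated (p-distance of 1) are recorded and skipped.

    Returns ``{"pvalues": list, "n_used": int, "n_skipped": int}``.
    """
    from .distances import DistanceError, distance_matrix
    from .intragroup_test import intra_group_distances, mc_pvalue, u_statistic

    base = config if config is not None else SimulationConfig()
    if base.implant is None:
        raise SimulationError("config must carry an implant spec (pi scales it)")
    pvalues: list[float] = []
    skipped = 0
    for i in range(n_reps):
        cfg = replace(
            base, seed=seed + i, implant=replace(base.implant, prob=pi)
        )
        ds = simulate_dataset(cfg)
        try:
            matrix = distance_matrix(ds.fragments()[domain])
        except DistanceError:
            skipped += 1
            continue
        ht = [r.species_id for r in ds.species if r.group == "hypoxic"]
        hs = [r.species_id for r in ds.species if r.group == "non_stress"]
        u = u_statistic(
            intra_group_distances(matrix, ht),
            intra_group_distances(matrix, hs),
            tie_rule=tie_rule,
        )
        pvalues.append(mc_pvalue(u, null_sample, tail=tail))
    return {"pvalues": pvalues, "n_used": len(pvalues), "n_skipped": skipped}


#: Study conditions for the reference-species similarity experiments: a
#: larger radiation (16 pairs) whose joins spread between 0.9 and 1.4 time
#: units, so a divergence-time threshold splits the species into graded
#: close/distant sets; the reference is the first HT leaf (itself a motif
#: carrier when pi > 0).
REFERENCE_STUDY_CONFIG = SimulationConfig(
    n_pairs=16,
    rate=0.3,
    cherry_depth=0.1,
    backbone_depths=tuple(0.9 + 0.5 * i / 14 for i in range(15)),
    implant=ImplantSpec(motif=parse_pattern("DLLAT"), domain="TAD2"),
)


def reference_study(
    n_reps: int,
    pi: float,
    domain: str = "TAD2",
    seed: int = 0,
    config: SimulationConfig | None = None,
    time_threshold: float = 2.3,
    alternative: str = "two_sided",
) -> dict:
    """Replicated reference-species close/distant analysis on synthetic data.

    Each replicate simulates a dataset in which the reference (the first HT
    leaf — the study organism whose motif is being tested, hence always a
    carrier) is implanted unconditionally and every other HT taxon with
    probability ``pi``. Species are classified as phylogenetically close by
    ``time_threshold`` on the true tree; the expected/observed tables, the
    adjusted Fisher p-value, and the observed count of HT species in the
    sequence-close set (the enrichment measure) are recorded. Saturated
    replicates are skipped and counted.

    Returns ``{"pvalues": [...], "ht_close": [...], "n_used": int,
    "n_skipped": int}``.
    """
    from .distances import DistanceError, distance_matrix, time_matrix
    from .reference_similarity import adjusted_fisher, close_distant_tables

    base = config if config is not None else REFERENCE_STUDY_CONFIG
    if base.implant is None:
        raise SimulationError("config must carry an implant spec (pi scales it)")
    ref = "pair01_HT"
    times = time_matrix(
        make_balanced_tree(base.n_pairs, base.cherry_depth, base.backbone_depths)
    )
    pvalues: list[float] = []
    ht_close: list[int] = []
    skipped = 0
    for i in range(n_reps):
        cfg = replace(
            base,
            seed=seed + i,
            implant=replace(base.implant, prob=pi, always=(ref,)),
        )
        ds = simulate_dataset(cfg)
        try:
            matrix = distance_matrix(ds.fragments()[domain])
        except DistanceError:
            skipped += 1
            continue
        with warnings.catch_warnings():
            # the reference is itself an HT species; its exclusion from the
            # counts is intended, not worth one warning per replicate
            warnings.simplefilter("ignore", UserWarning)
            tables = close_distant_tables(
                ds.species, matrix, ref,
                time_threshold=time_threshold, times=times,
            )
        pvalues.append(adjusted_fisher(tables, alternative=alternative))
        ht_close.append(int(tables.observed[0, 0]))
    return {
        "pvalues": pvalues,
        "ht_close": ht_close,
        "n_used": len(pvalues),
        "n_skipped": skipped,
    }


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def emit(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment FASTA, species TSV, newick, domain map and truth
    JSON; :func:`load_dataset` reproduces the dataset exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "species": out / "species.tsv",
        "tree": out / "tree.nwk",
        "domains": out / "domains.cfg",
        "truth": out / "truth.json",
    }
    write_alignment(dataset.alignment, paths["alignment"])
    write_species_table(dataset.species, paths["species"])
    paths["tree"].write_text(dataset.tree + "\n")
    with open(paths["domains"], "w") as fh:
        for name, dom in dataset.domains.items():
            fh.write(f"domain.{name} = {dom.ref_start}-{dom.ref_end}\n")
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    return paths


def load_dataset(out_dir: str | Path) -> SimulatedDataset:
    """Inverse of :func:`emit`."""
    out = Path(out_dir)
    from .core_io import read_domain_map  # local import avoids cycle at module load

    return SimulatedDataset(
        alignment=read_alignment(out / "alignment.fasta"),
        species=tuple(read_species_table(out / "species.tsv")),
        tree=(out / "tree.nwk").read_text().strip(),
        domains=read_domain_map(out / "domains.cfg"),
        truth=json.loads((out / "truth.json").read_text()),
    )
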