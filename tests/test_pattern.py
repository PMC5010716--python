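"""Motif grammar, scanning, and exact enrichment tests."""

import itertools
import re
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

import p53conv as pc
from p53conv.pattern_analysis import (
    Any_,
    Fixed,
    PatternError,
    ResidueClass,
    read_pattern_file,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def to_regex(pattern: pc.MotifPattern) -> str:
    """Independent oracle: translate the grammar into a regex."""
    parts = []
    for tok in pattern.tokens:
        if isinstance(tok, Fixed):
            parts.append(tok.residue)
        elif isinstance(tok, Any_):
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(tok.residues)) + "]")
    return "".join(parts)


class TestGrammar:
    @pytest.mark.parametrize(
        "text", ["LLXXE", "[DE]LLX[ST]", "KXXGE", "LM", "[DE]XX[AV]XWL"]
    )
    def test_parse_render_round_trip(self, text):
        assert pc.render_pattern(pc.parse_pattern(text)) == text

    def test_token_kinds(self):
        pat = pc.parse_pattern("[DE]LX")
        assert pat.tokens == (
            ResidueClass(frozenset("DE")), Fixed("L"), Any_()
        )

    @pytest.mark.parametrize("bad", ["", "L[DE", "L]E", "[ ]", "L1E", "[]L"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            pc.parse_pattern(bad)


class TestScanMotif:
    @pytest.mark.parametrize(
        "seq, pattern, hits",
        [
            ("ELLAT", "[DE]LLX[ST]", [1]),
            ("ALLQWEA", "LLXXE", [2]),
            ("MLSPE", "LLXXE", []),
            ("LMLMLM", "LM", [1, 3, 5]),
            ("AAAA", "AA", [1, 2, 3]),  # overlaps reported
        ],
    )
    def test_hand_examples(self, seq, pattern, hits):
        assert pc.scan_motif(seq, pc.parse_pattern(pattern)) == hits

    def test_gapped_sequence_rejected(self):
        with pytest.raises(PatternError, match="gap-free"):
            pc.scan_motif("LL-XE", pc.parse_pattern("LM"))

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        patterns = [
            pc.parse_pattern(t)
            for t in ("LLXXE", "[DE]LLX[ST]", "KXXGE", "LM", "[ACD]X[ACD]")
        ]
        regexes = [re.compile(f"(?=({to_regex(p)}))") for p in patterns]
        # a reduced alphabet makes matches frequent enough to be informative
        alphabet = np.array(list("ACDEKLMST"))
        for _ in range(2000):
            seq = "".join(rng.choice(alphabet, size=30))
            for pat, rx in zip(patterns, regexes):
                expected = [m.start() + 1 for m in rx.finditer(seq)]
                assert pc.scan_motif(seq, pat) == expected


class TestComposite:
    signature = pc.CompositePattern(
        name="tad2_sig",
        motifs=(pc.parse_pattern("[DE]LLX[ST]"), pc.parse_pattern("[DE]XX[AV]XWL")),
        scope="TAD2",
    )

    def test_both_motifs_in_order(self):
        assert pc.has_composite("AELLATADQAVAWLA", self.signature)

    def test_single_motif_insufficient(self):
        assert not pc.has_composite("AELLATAAAAAAAA", self.signature)

    def test_order_constraint_rejects_reversal(self):
        seq = "DQAAVWLAAADLLAT"  # second motif before the first
        assert not pc.has_composite(seq, self.signature)
        unordered = pc.CompositePattern(
            name="u", motifs=self.signature.motifs, order_constraint=False
        )
        assert pc.has_composite(seq, unordered)

    def test_needs_two_motifs(self):
        with pytest.raises(PatternError, match="at least 2"):
            pc.CompositePattern(name="x", motifs=(pc.parse_pattern("LM"),))


class TestPresenceMatrix:
    def test_matches_implantation_truth(self, implanted_dataset):
        frags = {
            name: pc.DomainFragmentSet(domain=name, fragments=f, columns=())
            for name, f in implanted_dataset.fragments().items()
        }
        pattern = pc.parse_pattern("[DE]LLX[ST]", name="sig", scope="TAD2")
        pm = pc.presence_matrix(frags, implanted_dataset.species, [pattern])
        carriers = set(implanted_dataset.truth["carriers"])
        assert set(pm.table.index[pm.table["sig"]]) == carriers

    def test_empty_pattern_list_gives_zero_width(self, implanted_dataset):
        frags = {
            name: pc.DomainFragmentSet(domain=name, fragments=f, columns=())
            for name, f in implanted_dataset.fragments().items()
        }
        pm = pc.presence_matrix(frags, implanted_dataset.species, [])
        assert pm.table.shape == (10, 0)

    def test_unknown_scope_rejected(self, implanted_dataset):
        frags = {
            name: pc.DomainFragmentSet(domain=name, fragments=f, columns=())
            for name, f in implanted_dataset.fragments().items()
        }
        with pytest.raises(PatternError, match="scope"):
            pc.presence_matrix(
                frags, implanted_dataset.species,
                [pc.parse_pattern("LM", scope="DBD")],
            )


def random_tables(rng, n, shape, max_total):
    for _ in range(n):
        while True:
            t = rng.integers(0, 6, size=shape)
            if 0 < t.sum() <= max_total:
                yield t
                break


class TestFisher2x2:
    def test_diagonal_corner(self):
        assert pc.fisher_2x2([[5, 0], [0, 5]], "greater") == pytest.approx(1 / 252)

    def test_hypergeometric_tail(self):
        assert pc.fisher_2x2([[3, 1], [1, 3]], "greater") == pytest.approx(17 / 70)

    def test_central_case_matches_scipy(self):
        rng = np.random.default_rng(23)
        for t in random_tables(rng, 150, (2, 2), 40):
            if not (t.sum(0) > 0).all() or not (t.sum(1) > 0).all():
                continue
            for ours, theirs in (
                ("greater", "greater"), ("less", "less"), ("two_sided", "two-sided")
            ):
                assert pc.fisher_2x2(t, ours) == pytest.approx(
                    fisher_exact(t, alternative=theirs).pvalue, rel=1e-9
                ), t

    def test_tail_complement_identity(self):
        rng = np.random.default_rng(29)
        from scipy.stats import hypergeom

        for t in random_tables(rng, 50, (2, 2), 30):
            if not (t.sum(0) > 0).all() or not (t.sum(1) > 0).all():
                continue
            pmf = hypergeom(t.sum(), t[0].sum(), t[:, 0].sum()).pmf(t[0, 0])
            total = pc.fisher_2x2(t, "greater") + pc.fisher_2x2(t, "less") - pmf
            assert total == pytest.approx(1.0)

    def test_greater_p_increases_with_null_or(self):
        # the noncentral family is stochastically increasing in the odds
        # ratio, so a larger null OR makes the observed excess less extreme
        table = [[10, 3], [5, 12]]
        ors = [0.25, 0.5, 1.0, 2.0, 4.0]
        ps = [pc.fisher_2x2(table, "greater", null_or=o) for o in ors]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert pc.fisher_2x2([[0, 0], [3, 4]], "greater") == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(PatternError):
            pc.fisher_2x2([[1, 2], [3, 4]], null_or=0.0)
        with pytest.raises(PatternError):
            pc.fisher_2x2([[1, -2], [3, 4]])


class TestFisher2x3:
    def brute_force(self, t):
        """Independent oracle: distribute the row-1 items over labeled cells
        by enumerating subsets of column-labeled balls."""
        cols = t.sum(axis=0)
        balls = []
        for c, n in enumerate(cols):
            balls.extend([c] * n)
        row1 = t[0].sum()
        counts: dict[tuple, int] = {}
        for subset in itertools.combinations(range(len(balls)), row1):
            key = tuple(
                sum(1 for i in subset if balls[i] == c) for c in range(3)
            )
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        p_obs = counts[tuple(t[0])] / total
        return sum(v for k, v in counts.items() if v / total <= p_obs * (1 + 1e-12)) / total

    def test_uniform_table_is_one(self):
        assert pc.fisher_2x3([[1, 1, 1], [1, 1, 1]]) == pytest.approx(1.0)

    def test_degenerate_column_reduces_to_2x2(self):
        t23 = np.array([[4, 1, 0], [2, 5, 0]])
        assert pc.fisher_2x3(t23) == pytest.approx(
            pc.fisher_2x2(t23[:, :2], "two_sided")
        )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        checked = 0
        for t in random_tables(rng, 40, (2, 3), 15):
            if t[0].sum() == 0 or t[1].sum() == 0:
                continue
            assert pc.fisher_2x3(t) == pytest.approx(self.brute_force(t), rel=1e-9), t
            checked += 1
        assert checked >= 25

    def test_agrees_with_r_fisher_test(self, tmp_path):
        """Cross-check against the independent R implementation."""
        import subprocess

        tables = [
            [[5, 1, 0], [2, 4, 6]],
            [[3, 3, 3], [1, 5, 2]],
            [[8, 0, 1], [2, 6, 3]],
        ]
        script = tmp_path / "fisher.R"
        lines = ["options(digits=15)"]
        for t in tables:
            lines.append(
                f"cat(fisher.test(matrix(c({t[0][0]},{t[1][0]},{t[0][1]},"
                f"{t[1][1]},{t[0][2]},{t[1][2]}),nrow=2))$p.value, '\\n')"
            )
        script.write_text("\n".join(lines))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_values = [float(x) for x in out.stdout.split()]
        for t, r_p in zip(tables, r_values):
            assert pc.fisher_2x3(t) == pytest.approx(r_p, rel=1e-9)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(PatternError, match="enumeration bound"):
            pc.fisher_2x3([[100, 100, 100], [1, 1, 1]])


class TestEnrichmentReport:
    def make_pm(self, k_hyp, n_hyp, k_met, n_met, k_non, n_non):
        ids, groups, present = [], [], []
        for prefix, k, n, g in (
            ("h", k_hyp, n_hyp, "hypoxic"),
            ("m", k_met, n_met, "metabolic"),
            ("n", k_non, n_non, "non_stress"),
        ):
            for i in range(n):
                ids.append(f"{prefix}{i}")
                groups.append(g)
                present.append(i < k)
        import pandas as pd

        return pc.PresenceMatrix(
            table=pd.DataFrame({"pat": present}, index=ids, dtype=bool),
            groups=pd.Series(groups, index=ids),
        )

    def test_corner_probability(self):
        pm = self.make_pm(15, 15, 0, 1, 0, 16)
        report = pc.pattern_enrichment_report(
            pm, comparisons=[("hypoxic", "non_stress")], three_way=None
        )
        assert report.loc[0, "p_hypoxic_vs_non_stress"] == pytest.approx(
            1 / comb(31, 15)
        )
        assert bool(report.loc[0, "screen"]) is True

    def test_ubiquitous_pattern_uninformative(self):
        pm = self.make_pm(5, 5, 6, 6, 7, 7)
        report = pc.pattern_enrichment_report(pm)
        assert report.loc[0, "p_hypoxic_vs_non_stress"] == 1.0
        assert report.loc[0, "p_2x3"] == pytest.approx(1.0)
        assert bool(report.loc[0, "screen"]) is False

    def test_screen_threshold_boundary(self):
        pm = self.make_pm(4, 8, 1, 8, 0, 8)
        report = pc.pattern_enrichment_report(pm, screen_p=0.005)
        p = report.loc[0, "p_hypoxic_vs_non_stress"]
        assert bool(report.loc[0, "screen"]) == (p < 0.005)


class TestPredictorMatrix:
    def test_residue_table(self, toy_alignment):
        df = pc.predictor_matrix(toy_alignment, [2, 4, 6])
        assert df.shape == (4, 3)
        assert df.loc["whale", "pos4"] == "-"
        assert df.loc["spalax", "pos2"] == "Q"

    def test_one_hot_counts_distinct_residues(self, toy_alignment):
        df = pc.predictor_matrix(toy_alignment, [2], one_hot=True)
        # column 2 holds E,E,E,Q -> two indicators
        assert sorted(df.columns) == ["pos2=E", "pos2=Q"]
        assert df["pos2=E"].sum() == 3

    def test_gap_is_its_own_category(self, toy_alignment):
        df = pc.predictor_matrix(toy_alignment, [6], one_hot=True)
        assert "pos6=-" in df.columns

    def test_invalid_column_rejected(self, toy_alignment):
        with pytest.raises(PatternError, match="outside"):
            pc.predictor_matrix(toy_alignment, [0])


class TestPatternFile:
    def test_read_mixed_patterns(self, tmp_path):
        path = tmp_path / "patterns.tsv"
        path.write_text(
            "# stress-associated motifs\n"
            "llxxe\tTAD2\tLLXXE\n"
            "sig\tTAD2\t[DE]LLX[ST] + [DE]XX[AV]XWL\n"
        )
        pats = read_pattern_file(path)
        assert isinstance(pats[0], pc.MotifPattern)
        assert pats[0].scope == "TAD2"
        assert isinstance(pats[1], pc.CompositePattern)
        assert len(pats[1].motifs) == 2

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("just-one-field\n")
        with pytest.raises(PatternError, match="expected"):
            read_pattern_file(path)
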