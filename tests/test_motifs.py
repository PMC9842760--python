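"""Tests for PWM scoring, two-strand scanning, presence logic and the
two-tailed hypergeometric enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isgland.motifs import (
    ExactMotif,
    PWM,
    hypergeometric_enrichment,
    motif_presence,
    reverse_complement,
    scan_sequences,
    two_tailed_hypergeom_p,
    upper_tail_hypergeom_p,
)

SEQ = st.text(alphabet="ACGT", min_size=12, max_size=60)


def single_site_pwm(site, pseudocount=0.0, threshold=0.8):
    counts = np.zeros((4, len(site)))
    for j, b in enumerate(site):
        counts["ACGT".index(b), j] = 1
    return PWM.from_counts("test", counts, pseudocount=pseudocount,
                           threshold_fraction=threshold)


class TestScoring:
    def test_single_site_pwm_scores_its_site_at_two_bits_per_base(self):
        pwm = single_site_pwm("ACGT")
        assert pwm.score_window("ACGT") == pytest.approx(8.0)
        assert pwm.max_score == pytest.approx(8.0)

    def test_all_n_window_scores_zero(self):
        pwm = single_site_pwm("ACGT", pseudocount=0.01)
        assert pwm.score_window("NNNN") == pytest.approx(0.0)

    def test_random_pwm_matches_position_by_position_sum(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(4, 8)).astype(float)
        pwm = PWM.from_counts("rand", counts)
        window = "".join(rng.choice(list("ACGT"), 8))
        # brute-force oracle: explicit per-position log-odds sum
        reg = counts + pwm.pseudocount
        probs = reg / reg.sum(axis=0)
        expected = sum(
            math.log2(probs["ACGT".index(b), j] / 0.25)
            for j, b in enumerate(window)
        )
        assert pwm.score_window(window) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            single_site_pwm("ACGT").score_window("ACG")

    def test_ambiguity_codes_other_than_n_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            single_site_pwm("ACGT").scan("s", "ACGRTACG")


class TestScanning:
    def test_ire_forward_hit_position(self):
        ire = ExactMotif("IRE", "TTTC")
        hits = ire.scan("s", "AATTTCGG")
        assert [(h.start, h.strand) for h in hits] == [(2, "+")]

    def test_ire_reverse_strand_hit(self):
        ire = ExactMotif("IRE", "TTTC")
        hits = ire.scan("s", "CCGAAATT")
        assert len(hits) == 1 and hits[0].strand == "-"
        # the reverse complement of the sequence carries TTTC at the mapped spot
        rc = reverse_complement("CCGAAATT")
        start_rc = len(rc) - 4 - hits[0].start
        assert rc[start_rc : start_rc + 4] == "TTTC"

    @settings(max_examples=80, derandomize=True)
    @given(SEQ)
    def test_strand_symmetry_under_reverse_complement(self, seq):
        """Hits on a sequence and its reverse complement are bijective with
        strands flipped and coordinates mirrored."""
        pwm = single_site_pwm("AGTTTC", pseudocount=0.05, threshold=0.75)
        fwd = {(h.start, h.strand) for h in pwm.scan("s", seq)}
        rc = {(h.start, h.strand) for h in pwm.scan("s", reverse_complement(seq))}
        L, n = pwm.length, len(seq)
        mirrored = {
            (n - L - start, "+" if strand == "-" else "-") for start, strand in rc
        }
        assert fwd == mirrored

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500))
        counts = rng.integers(1, 30, size=(4, 6)).astype(float)
        previous = None
        for frac in (0.5, 0.7, 0.9, 1.0):
            pwm = PWM.from_counts("m", counts, threshold_fraction=frac)
            n_hits = len(pwm.scan("s", seq))
            if previous is not None:
                assert n_hits <= previous
            previous = n_hits

    def test_scan_sequences_tidy_table(self, motif_set):
        seqs = {"a": "AAAAGTTTCAGTTTCAAAA", "b": "CCCCCCCCCCCCCCCC"}
        hits = scan_sequences(motif_set, seqs)
        assert set(hits.columns) == {"seq_id", "motif", "start", "strand", "score"}
        assert "ISRE" in set(hits.loc[hits["seq_id"] == "a", "motif"])


class TestPresence:
    def _hits(self):
        return pd.DataFrame(
            {
                "seq_id": ["p1", "p2"],
                "motif": ["ISRE", "NFKB"],
                "start": [0, 0],
                "strand": ["+", "+"],
                "score": [10.0, 10.0],
            }
        )

    def test_isre_hit_in_promoter_gives_presence(self):
        pres = motif_presence(self._hits(), {"gene1": ["p1"]}, ["ISRE", "GAS"])
        assert bool(pres["gene1"])

    def test_nfkb_only_gene_absent_for_isre_gas_query(self):
        pres = motif_presence(self._hits(), {"gene2": ["p2"]}, ["ISRE", "GAS"])
        assert not bool(pres["gene2"])

    def test_gene_without_regions_warns_false(self):
        with pytest.warns(UserWarning, match="no mapped regions"):
            pres = motif_presence(self._hits(), {"gene3": []}, ["ISRE"])
        assert not bool(pres["gene3"])


def exact_two_tailed_oracle(k, n, K, N):
    """Independent enumeration oracle in exact rational arithmetic."""
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = {
        x: Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
        for x in range(lo, hi + 1)
    }
    return float(sum(p for p in pmf.values() if p <= pmf[k]))


class TestHypergeometric:
    def test_upper_tail_worked_example(self):
        # N=10, K=4, n=5, k=4: P(X >= 4) = C(4,4) C(6,1) / C(10,5) = 6/252
        assert upper_tail_hypergeom_p(4, 5, 4, 10) == pytest.approx(6 / 252)

    def test_two_tailed_worked_example_matches_enumeration(self):
        assert two_tailed_hypergeom_p(4, 5, 4, 10) == pytest.approx(
            exact_two_tailed_oracle(4, 5, 4, 10), abs=1e-15
        )

    def test_grid_against_enumeration_oracle(self):
        for N in range(2, 41, 3):
            for K in {0, 1, N // 3, N // 2, N}:
                for n in {1, N // 2, N}:
                    if n == 0:
                        continue
                    lo, hi = max(0, n - (N - K)), min(n, K)
                    for k in range(lo, hi + 1):
                        got = two_tailed_hypergeom_p(k, n, K, N)
                        assert got == pytest.approx(
                            exact_two_tailed_oracle(k, n, K, N), abs=1e-12
                        )

    def test_agrees_with_scipy_point_probabilities(self):
        # cross-check the pmf underlying the rule against scipy's hypergeom
        N, K, n = 30, 12, 9
        ours = [
            float(
                Fraction(
                    math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n)
                )
            )
            for x in range(0, n + 1)
        ]
        theirs = stats.hypergeom.pmf(range(0, n + 1), N, K, n)
        assert ours == pytest.approx(list(theirs), abs=1e-13)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_hypergeom_p(5, 4, 6, 10)


class TestEnrichment:
    def _hits(self, hit_map):
        rows = [
            {"seq_id": r, "motif": m, "start": 0, "strand": "+", "score": 1.0}
            for m, regions in hit_map.items()
            for r in regions
        ]
        return pd.DataFrame(rows)

    def test_foreground_equals_background_gives_p_one(self):
        bg = [f"r{i}" for i in range(8)]
        hits = self._hits({"ISRE": bg[:3]})
        res = hypergeometric_enrichment(bg, bg, hits, ["ISRE"])
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)
        assert res["k"].iloc[0] == res["K"].iloc[0]

    def test_matched_rates_give_unit_fold(self):
        bg = [f"r{i}" for i in range(10)]
        fg = bg[:5]
        hits = self._hits({"ISRE": ["r0", "r1", "r5", "r6"]})  # 2/5 vs 4/10
        res = hypergeometric_enrichment(fg, bg, hits, ["ISRE"])
        assert res["fold_enrichment"].iloc[0] == pytest.approx(1.0)

    def test_foreground_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["x"], ["a", "b"], self._hits({"ISRE": []}), ["ISRE"])

    def test_relabeling_regions_preserves_p(self):
        bg = [f"r{i}" for i in range(12)]
        fg = bg[:4]
        hits = self._hits({"ISRE": ["r0", "r1", "r2", "r8"]})
        res1 = hypergeometric_enrichment(fg, bg, hits, ["ISRE"])
        relabel = {r: f"z{i}" for i, r in enumerate(bg)}
        hits2 = self._hits({"ISRE": [relabel[r] for r in ["r0", "r1", "r2", "r8"]]})
        res2 = hypergeometric_enrichment(
            [relabel[r] for r in fg], list(relabel.values()), hits2, ["ISRE"]
        )
        assert res1["pvalue"].iloc[0] == pytest.approx(res2["pvalue"].iloc[0], abs=1e-15)

    def test_padj_adjusts_across_motifs(self):
        bg = [f"r{i}" for i in range(20)]
        fg = bg[:10]
        hits = self._hits({"ISRE": fg, "GAS": bg[5:15], "NFKB": bg[::2]})
        res = hypergeometric_enrichment(fg, bg, hits, ["ISRE", "GAS", "NFKB"])
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()
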