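"""Variant filtering, strand/track classification, motif annotation, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutascope import (
    annotate_motif,
    classify_strand_and_track,
    filter_variants,
    revcomp,
    summarize_outcomes,
)


def table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "af"])


class TestFilterVariants:
    def test_allele_fraction_thresholds(self):
        df = table([
            ("s1", "chrIII", 100, "C", "T", 0.30),   # below 0.35: removed
            ("s1", "chrIII", 200, "C", "T", 0.35),   # at threshold: kept
            ("s1", "chrIII", 300, "C", "T", 0.50),   # heterozygous
            ("s1", "chrIII", 400, "C", "T", 0.85),   # homozygous boundary
            ("s1", "chrIII", 500, "C", "T", 0.90),   # homozygous
        ])
        out, report = filter_variants(df)
        assert list(out["pos"]) == [200, 300, 400, 500]
        assert list(out["zygosity"]) == [
            "heterozygous", "heterozygous", "homozygous", "homozygous"]
        assert report["n_removed_low_af"] == 1

    def test_threshold_boundary_is_configurable(self):
        df = table([("s1", "chrIII", 200, "C", "T", 0.35)])
        out, _ = filter_variants(df, keep_af_at_threshold=False)
        assert len(out) == 0

    def test_recurrent_variants_removed_from_all_samples(self):
        df = table([
            ("s1", "chrIII", 100, "C", "T", 0.5),
            ("s2", "chrIII", 100, "C", "T", 0.6),   # same variant, second sample
            ("s1", "chrIII", 100, "C", "G", 0.5),   # same position, different alt
            ("s2", "chrIII", 900, "C", "T", 0.5),
        ])
        out, report = filter_variants(df)
        assert report["n_removed_recurrent"] == 2
        assert set(zip(out["sample_id"], out["pos"], out["alt"])) == {
            ("s1", 100, "G"), ("s2", 900, "T")}

    def test_recurrence_filter_idempotent(self):
        rng = np.random.default_rng(0)
        df = table([
            (f"s{rng.integers(4)}", "chrIII", int(rng.integers(1, 50)) * 10,
             "C", "T", float(rng.uniform(0.36, 0.99)))
            for _ in range(60)
        ])
        once, _ = filter_variants(df)
        twice, _ = filter_variants(once.drop(columns="zygosity"))
        assert once.reset_index(drop=True).equals(twice.reset_index(drop=True))

    def test_invalid_allele_fractions_reported(self):
        df = table([
            ("s1", "chrIII", 100, "C", "T", 1.2),
            ("s1", "chrIII", 200, "C", "T", 0.5),
        ])
        out, report = filter_variants(df)
        assert len(report["rejected_invalid_af"]) == 1
        assert list(out["pos"]) == [200]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_raising_threshold_never_increases_survivors(self, afs, higher):
        df = table([("s1", "chrIII", 10 * (i + 1), "C", "T", af)
                    for i, af in enumerate(afs)])
        base, _ = filter_variants(df, af_min=0.35)
        stricter, _ = filter_variants(df, af_min=max(0.35, higher))
        assert len(stricter) <= len(base)


class TestClassification:
    def test_strand_class_and_track(self, genome):
        df = table([
            ("s1", "chrIII", 250_000, "C", "T", 0.5),   # on track
            ("s1", "chrIII", 50_000, "G", "A", 0.5),    # left arm
            ("s1", "chrIII", 150_000, "G", "A", 0.5),   # right arm, off track
            ("s1", "chrI", 10_000, "A", "T", 0.5),      # neither C nor G
            ("s1", "chrI", 10_001, "AT", "A", 0.5),     # indel
        ])
        out = classify_strand_and_track(df, genome)
        assert list(out["strand_class"]) == ["CtoN", "GtoN", "GtoN", "other", "other"]
        assert list(out["on_track"]) == [True, False, False, False, False]
        assert list(out["arm"]) == ["right", "left", "right", "left", "left"]
        assert out["mutation_type"].iloc[0] == "C>T"
        assert out["mutation_type"].iloc[4] == "indel"

    def test_position_beyond_chromosome_rejected(self, genome):
        df = table([("s1", "chrIII", 400_000, "C", "T", 0.5)])
        with pytest.raises(ValueError):
            classify_strand_and_track(df, genome)

    def test_every_snv_in_one_class_and_one_arm(self, genome, reference):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            pos = int(rng.integers(3, 319_000))
            ref_base = reference["chrIII"][pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            rows.append(("s1", "chrIII", pos, ref_base, alt, 0.5))
        out = classify_strand_and_track(table(rows), genome)
        assert out["strand_class"].isin(["CtoN", "GtoN", "other"]).all()
        assert out["arm"].isin(["left", "right"]).all()
        assert ((out["ref"] == "C") == (out["strand_class"] == "CtoN")).all()
        assert ((out["ref"] == "G") == (out["strand_class"] == "GtoN")).all()


class TestMotifAnnotation:
    @pytest.mark.parametrize("left,right", [(a, b) for a in "ACGT" for b in "ACGT"])
    def test_all_sixteen_contexts_against_revcomp_oracle(self, left, right):
        """C>N at the Watson triplet and G>N at the mirrored Crick triplet agree
        with a direct reverse-complement oracle."""
        ref = {"c": f"AA{left}C{right}AA", "g": f"AA{revcomp(right)}G{revcomp(left)}AA"}
        df = pd.DataFrame({
            "sample_id": ["s", "s"], "chrom": ["c", "g"], "pos": [4, 4],
            "ref": ["C", "G"], "alt": ["T", "A"], "af": [0.5, 0.5],
            "strand_class": ["CtoN", "GtoN"],
        })
        out = annotate_motif(df, ref)
        expected = f"{left}C{right}" in ("TCA", "TCT")
        assert bool(out["tcw"].iloc[0]) is expected
        # the Crick-strand triplet of the "g" contig is the Watson triplet of "c"
        assert bool(out["tcw"].iloc[1]) is expected

    def test_contig_edge_flagged(self):
        ref = {"c": "CAT"}
        df = pd.DataFrame({
            "sample_id": ["s"], "chrom": ["c"], "pos": [1],
            "ref": ["C"], "alt": ["T"], "af": [0.5], "strand_class": ["CtoN"],
        })
        out = annotate_motif(df, ref)
        assert out["tcw"].isna().iloc[0]
        assert not out["tcw_defined"].iloc[0]


class TestSummaries:
    def test_mean_per_outcome(self, genome):
        """13 track G>A mutations over 62 outcomes give a mean of 0.21."""
        rows = [(f"s{i:02d}", "chrIII", 200_100 + 7 * i, "G", "A", 0.5)
                for i in range(13)]
        df = classify_strand_and_track(table(rows), genome)
        samples = {"UNG1": [f"s{i:02d}" for i in range(62)]}
        summary = summarize_outcomes(
            df, groups={s: "UNG1" for s in df["sample_id"]}, samples=samples)["UNG1"]
        assert summary.n_samples == 62
        assert summary.track_count("GtoN", "G>A") == 13
        assert summary.track_mean("GtoN", "G>A") == pytest.approx(0.21, abs=0.005)

    def test_zero_variant_sample(self, genome):
        df = classify_strand_and_track(table([]).astype(
            {"pos": int, "af": float}), genome)
        summary = summarize_outcomes(df, groups={}, samples={"g": ["s1"]})["g"]
        assert summary.n_samples == 1
        assert summary.track_count("CtoN") == 0

    def test_spectrum_fractions_sum_to_one(self, genome):
        rng = np.random.default_rng(2)
        rows = [("s1", "chrIII", int(p), r, a, 0.5) for p, r, a in zip(
            rng.integers(1, 300_000, 50),
            rng.choice(["C", "G"], 50),
            rng.choice(["T", "A"], 50))]
        rows = [(s, c, p, r, a, f) for s, c, p, r, a, f in rows if r != a]
        df = classify_strand_and_track(table(rows), genome)
        summary = summarize_outcomes(df)["all"]
        assert summary.spectrum.sum() == pytest.approx(1.0)
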