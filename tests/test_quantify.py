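"""Mode-specific read counting, total TERRA, CPM and poly(A) statistics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from terrakit.annotate import TerraRegion
from terrakit.promoter_elements import PromoterSignature
from terrakit.quantify import (
    CountMatrix,
    correlate,
    count_reads,
    cpm,
    polya_enrichment,
    total_terra,
)
from terrakit.repeatscan import AlignmentRecord


def region(rid, start, end, tract_start, seq_id="chr1", strand="+",
           rtype="I", category="terminal_q", rank="proximal"):
    if strand == "+":
        sub, tss = (start, tract_start), start
        telo = (tract_start, end)
    else:
        sub, tss = (tract_start, end), end
        telo = (start, tract_start)
    r = TerraRegion(
        region_id=rid, seq_id=seq_id, start=start, end=end, strand=strand,
        tss=tss, subtelomeric=sub, telomeric=telo, type=rtype,
        signature=PromoterSignature(rtype == "I", False, rtype == "I"),
        tss_rank=rank,
        tract_category="interstitial" if rtype == "III" else category,
    )
    r.validate()
    return r


def pair(read_id, seq_id, start, end, mapq=60, duplicate=False, strand="+",
         read_len=50):
    rev = strand == "-"
    common = dict(read_id=read_id, seq_id=seq_id, mapq=mapq, paired=True,
                  proper_pair=True, primary=True, duplicate=duplicate)
    return [
        AlignmentRecord(start=start, end=min(start + read_len, end),
                        reverse_strand=rev, first_in_pair=True, **common),
        AlignmentRecord(start=max(end - read_len, start), end=end,
                        reverse_strand=not rev, first_in_pair=False, **common),
    ]


class TestCountReads:
    def test_fragment_inside_region_counts_once(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        cm = count_reads(pair("f1", "chr1", 1200, 1500), regions, mode="total")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 1
        assert cm.counts["sample"]["chr1q:telomeric"] == 0

    def test_straddling_fragment_counts_in_both_features(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        cm = count_reads(pair("f1", "chr1", 1900, 2100), regions, mode="total")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 1
        assert cm.counts["sample"]["chr1q:telomeric"] == 1

    def test_arm_specific_requires_mapq30_and_subtelomere(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        records = (pair("hi", "chr1", 1100, 1400, mapq=60)
                   + pair("lo", "chr1", 1100, 1400, mapq=10)
                   + pair("telo", "chr1", 2100, 2400, mapq=60))
        cm = count_reads(records, regions, mode="arm_specific")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 1
        assert cm.counts["sample"]["chr1q:telomeric"] == 0

    def test_total_mode_removes_duplicates_keeps_low_mapq(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        records = (pair("a", "chr1", 1100, 1400, mapq=5)
                   + pair("b", "chr1", 1100, 1400, duplicate=True))
        cm = count_reads(records, regions, mode="total")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 1

    def test_positional_dedup_when_no_flags(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        records = (pair("a", "chr1", 1100, 1400) + pair("b", "chr1", 1100, 1400)
                   + pair("c", "chr1", 1150, 1400))
        cm = count_reads(records, regions, mode="total")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 2

    def test_single_end_unique_mapq255(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        records = [
            AlignmentRecord("a", "chr1", 1100, 1200, mapq=255),
            AlignmentRecord("b", "chr1", 1100, 1200, mapq=60),
        ]
        cm = count_reads(records, regions, mode="arm_specific",
                         library_layout="single")
        assert cm.counts["sample"]["chr1q:subtelomeric"] == 1

    def test_strandedness(self):
        regions = [region("chr1q", 1000, 3000, 2000)]
        fwd = pair("f", "chr1", 1100, 1400, strand="+")
        rev = pair("r", "chr1", 1100, 1400, strand="-")
        fwd_cm = count_reads(fwd + rev, regions, strandedness="forward")
        rev_cm = count_reads(fwd + rev, regions, strandedness="reverse")
        assert fwd_cm.counts["sample"]["chr1q:subtelomeric"] == 1
        assert rev_cm.counts["sample"]["chr1q:subtelomeric"] == 1

    def test_order_invariance(self):
        regions = [region("chr1q", 1000, 3000, 2000),
                   region("chr2q", 500, 2500, 1500, seq_id="chr2", rtype="II")]
        records = sum(
            (pair(f"f{i}", "chr1", 1000 + 37 * i, 1500 + 41 * i) for i in range(20)),
            [],
        )
        fwd = count_reads(records, regions)
        rev = count_reads(records[::-1], regions)
        pd.testing.assert_frame_equal(fwd.counts, rev.counts)

    @pytest.mark.parametrize("config_seed", range(20))
    def test_matches_quadratic_oracle(self, config_seed):
        """Random fragments vs an independent quadratic overlap oracle
        applying the same MAPQ/flag/duplicate/strand rules, all modes."""
        rng = np.random.default_rng(1000 + config_seed)
        n_regions = int(rng.integers(1, 6))  # up to 10 sub-features
        regions = []
        cursor = 1000
        for i in range(n_regions):
            sub_len = int(rng.integers(300, 2000))
            telo_len = int(rng.integers(200, 1000))
            regions.append(
                region(f"r{i}q", cursor, cursor + sub_len + telo_len,
                       cursor + sub_len,
                       rtype=str(rng.choice(["I", "II", "III"])),
                       strand=str(rng.choice(["+", "-"])))
            )
            cursor += sub_len + telo_len + int(rng.integers(100, 500))
        layout = str(rng.choice(["paired", "single"]))
        strandedness = str(rng.choice(["none", "forward", "reverse"]))
        mode = str(rng.choice(["arm_specific", "total", "capture"]))

        records = []
        n_frags = int(rng.integers(20, 300))
        for i in range(n_frags):
            start = int(rng.integers(0, cursor))
            flen = int(rng.integers(100, 600))
            mapq = int(rng.choice([0, 5, 30, 60, 255]))
            dup = bool(rng.random() < 0.1)
            strand = str(rng.choice(["+", "-"]))
            if layout == "paired":
                records.extend(pair(f"f{i}", "chr1", start, start + flen,
                                    mapq=mapq, duplicate=dup, strand=strand))
            else:
                records.append(
                    AlignmentRecord(f"f{i}", "chr1", start, start + flen,
                                    mapq=mapq, duplicate=dup,
                                    reverse_strand=strand == "-")
                )
        got = count_reads(records, regions, mode=mode, library_layout=layout,
                          strandedness=strandedness)
        expected = self._oracle(records, regions, mode, layout, strandedness)
        assert dict(got.counts["sample"]) == expected

    @staticmethod
    def _oracle(records, regions, mode, layout, strandedness):
        """Brute-force reference: independent pairing, filtering, overlap."""
        # assemble fragments per read id
        frag = {}
        for r in records:
            if not r.primary:
                continue
            key = r.read_id
            if key not in frag:
                frag[key] = dict(seq=r.seq_id, lo=r.start, hi=r.end,
                                 dup=r.duplicate, mapq=r.mapq, strand=None)
            else:
                frag[key]["lo"] = min(frag[key]["lo"], r.start)
                frag[key]["hi"] = max(frag[key]["hi"], r.end)
                frag[key]["dup"] = frag[key]["dup"] or r.duplicate
                frag[key]["mapq"] = min(frag[key]["mapq"], r.mapq)
            if layout == "single" or r.first_in_pair:
                frag[key]["strand"] = r.strand
        frags = list(frag.values())
        if mode == "arm_specific":
            if layout == "paired":
                frags = [f for f in frags if f["mapq"] >= 30]
            else:
                frags = [f for f in frags if f["mapq"] == 255]
        elif mode == "capture":
            frags = [f for f in frags if f["mapq"] >= 30]
        else:
            frags = [f for f in frags if f["mapq"] >= 1]
            if any(f["dup"] for f in frags):
                frags = [f for f in frags if not f["dup"]]
            else:
                seen, uniq = set(), []
                for f in sorted(frags, key=lambda f: (f["seq"], f["lo"], f["hi"])):
                    k = (f["seq"], f["lo"], f["hi"], f["strand"])
                    if k not in seen:
                        seen.add(k)
                        uniq.append(f)
                frags = uniq
        # feature intervals
        feats = {}
        for r in regions:
            if mode == "capture":
                feats[r.region_id] = (r.seq_id, r.start, r.end, r.strand)
            else:
                if r.subtelomeric[1] > r.subtelomeric[0]:
                    feats[f"{r.region_id}:subtelomeric"] = (
                        r.seq_id, *r.subtelomeric, r.strand)
                if r.telomeric[1] > r.telomeric[0]:
                    feats[f"{r.region_id}:telomeric"] = (
                        r.seq_id, *r.telomeric, r.strand)
        out = {fid: 0 for fid in feats}
        for f in frags:
            for fid, (seq, lo, hi, strand) in feats.items():
                if f["seq"] != seq or f["hi"] <= lo or hi <= f["lo"]:
                    continue
                if mode == "arm_specific" and fid.endswith(":telomeric"):
                    continue
                if strandedness == "forward" and f["strand"] != strand:
                    continue
                if strandedness == "reverse" and f["strand"] == strand:
                    continue
                out[fid] += 1
        if mode == "arm_specific":
            out = {fid: n for fid, n in out.items()
                   if not fid.endswith(":telomeric")}
            # implementation reports telomeric features with zero counts
            for r in regions:
                if r.telomeric[1] > r.telomeric[0]:
                    out[f"{r.region_id}:telomeric"] = 0
        return out


class TestTotalTerra:
    def _matrix(self, entries):
        features = pd.DataFrame(
            [(fid, "chr1", 0, 1, "+", fid.split(":")[0], rtype, sub, rank)
             for fid, rtype, sub, rank, _count in entries],
            columns=["feature_id", "seq_id", "start", "end", "strand",
                     "region_id", "region_type", "subregion", "tss_rank"],
        ).set_index("feature_id")
        counts = pd.DataFrame(
            {"s1": [c for *_rest, c in entries]},
            index=features.index,
        )
        return CountMatrix(features, counts)

    def test_hand_built_matrix(self):
        cm = self._matrix([
            ("chr1q:subtelomeric", "I", "subtelomeric", "proximal", 5),
            ("chr1q:telomeric", "I", "telomeric", "proximal", 7),
            ("chr2q:subtelomeric", "II", "subtelomeric", "proximal", 3),
            ("ITS_chr3_1:subtelomeric", "III", "subtelomeric", "proximal", 100),
        ])
        assert total_terra(cm)["s1"] == 15

    def test_only_type_three_gives_zero(self):
        cm = self._matrix([
            ("ITS_chr1_1:subtelomeric", "III", "subtelomeric", "proximal", 40),
            ("ITS_chr1_1:telomeric", "III", "telomeric", "proximal", 10),
        ])
        assert total_terra(cm)["s1"] == 0

    def test_distal_tss_regions_excluded(self):
        cm = self._matrix([
            ("chr5q:subtelomeric", "I", "subtelomeric", "proximal", 8),
            ("chr5q_distal:subtelomeric", "I", "subtelomeric", "distal", 9),
        ])
        assert total_terra(cm)["s1"] == 8


class TestCpm:
    def _cm(self, values, samples=("s1",)):
        features = pd.DataFrame(
            {"seq_id": "chr1", "start": 0, "end": 1, "strand": "+",
             "region_id": [f"r{i}" for i in range(len(values))],
             "region_type": "I", "subregion": "subtelomeric",
             "tss_rank": "proximal"},
            index=pd.Index([f"r{i}" for i in range(len(values))], name="feature_id"),
        )
        counts = pd.DataFrame({s: values for s in samples}, index=features.index)
        return CountMatrix(features, counts)

    def test_simple_value(self):
        cm = self._cm([50])
        assert cpm(cm, {"s1": 1_000_000}).iloc[0, 0] == 50.0

    def test_zero_count(self):
        assert cpm(self._cm([0]), {"s1": 10_000}).iloc[0, 0] == 0.0

    def test_scale_invariance(self):
        cm1 = self._cm([10, 20, 30])
        cm2 = self._cm([20, 40, 60])
        a = cpm(cm1, {"s1": 1_000})
        b = cpm(cm2, {"s1": 2_000})
        pd.testing.assert_frame_equal(a, b)

    def test_missing_library_size_rejected(self):
        with pytest.raises(ValueError):
            cpm(self._cm([1]), {})


class TestPolyA:
    def _cm(self, counts_by_region, sample):
        rids = list(counts_by_region)
        features = pd.DataFrame(
            {"seq_id": "chr1", "start": 0, "end": 1, "strand": "+",
             "region_id": rids, "region_type": "I", "subregion": "region",
             "tss_rank": "proximal"},
            index=pd.Index(rids, name="feature_id"),
        )
        counts = pd.DataFrame({sample: list(counts_by_region.values())},
                              index=features.index)
        return CountMatrix(features, counts)

    def test_identical_fractions_give_zero_ratios(self):
        cm = self._cm({"a": 30, "b": 70}, "plus")
        cm2 = self._cm({"a": 30, "b": 70}, "minus")
        for r in polya_enrichment(cm, cm2):
            assert r.log2_ratio == pytest.approx(0.0)

    def test_twenty_over_five_percent_gives_two(self):
        plus = self._cm({"a": 20, "b": 80}, "plus")
        minus = self._cm({"a": 5, "b": 95}, "minus")
        res = {r.region_id: r for r in polya_enrichment(plus, minus)}
        assert res["a"].frac_plus == pytest.approx(0.20)
        assert res["a"].frac_minus == pytest.approx(0.05)
        assert res["a"].log2_ratio == pytest.approx(2.0)

    def test_swap_negates_finite_ratios(self):
        plus = self._cm({"a": 20, "b": 30, "c": 50}, "plus")
        minus = self._cm({"a": 10, "b": 60, "c": 30}, "minus")
        fwd = polya_enrichment(plus, minus)
        rev = polya_enrichment(minus, plus)
        for f, r in zip(fwd, rev):
            assert f.log2_ratio == pytest.approx(-r.log2_ratio)

    def test_fractions_sum_to_one(self):
        plus = self._cm({"a": 13, "b": 29, "c": 58}, "plus")
        minus = self._cm({"a": 7, "b": 11, "c": 2}, "minus")
        res = polya_enrichment(plus, minus)
        assert sum(r.frac_plus for r in res) == pytest.approx(1.0, abs=1e-9)
        assert sum(r.frac_minus for r in res) == pytest.approx(1.0, abs=1e-9)

    def test_zero_region_flagged_undefined(self):
        plus = self._cm({"a": 0, "b": 10}, "plus")
        minus = self._cm({"a": 5, "b": 5}, "minus")
        res = {r.region_id: r for r in polya_enrichment(plus, minus)}
        assert not res["a"].defined
        assert math.isnan(res["a"].log2_ratio)

    def test_all_zero_fraction_rejected(self):
        plus = self._cm({"a": 0}, "plus")
        minus = self._cm({"a": 5}, "minus")
        with pytest.raises(ValueError):
            polya_enrichment(plus, minus)


class TestCorrelate:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, x)[0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, _ = correlate(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)


def test_simulated_total_mode_counts_match_truth(sim_short_reads, sim_truth):
    """On disjoint planted regions, region-level total-mode counts equal
    the number of non-duplicate fragments the simulator drew per region."""
    cm = count_reads(sim_short_reads, sim_truth.regions, mode="total",
                     feature_level="region")
    dup_ids = {r.read_id for r in sim_short_reads if r.duplicate}
    expected = {}
    for rid in {r.read_id for r in sim_short_reads} - dup_ids:
        origin = sim_truth.read_origin[rid]
        if origin != "background":
            expected[origin] = expected.get(origin, 0) + 1
    assert {k: int(v) for k, v in cm.counts["sample"].items()} == expected


def test_arm_specific_never_exceeds_total_on_nested_sim():
    """With no duplicates the arm filter (MAPQ >= 30) is nested inside the
    total filter (MAPQ >= 1), so arm counts cannot exceed total counts.
    (With duplicates the filters are not nested: only total mode dedups.)"""
    from terrakit import simdata

    cfg = simdata.default_config(seed=21)
    cfg.short_reads.duplicate_frac = 0.0
    _, truth = simdata.simulate_genome(cfg)
    records, truth = simdata.simulate_short_reads(truth, cfg)
    arm = count_reads(records, truth.regions, mode="arm_specific")
    total = count_reads(records, truth.regions, mode="total")
    sub = arm.features["subregion"] == "subtelomeric"
    assert (arm.counts.loc[sub, "sample"] <= total.counts.loc[sub, "sample"]).all()
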