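import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import peakgene as pg
from peakgene import aggregate as agg
from peakgene.errors import (AggregatorError, GenomeMismatchError,
                             RangeValidationError)

from _bruteforce import brute_join, brute_merge, records


def rt(rows, **kw):
    return pg.validate_ranges(pd.DataFrame(rows), **kw)


class TestValidateRanges:
    def test_identity_and_default_strand(self):
        t = rt([{"seqname": "chr1", "start": 5, "end": 10}])
        assert list(t.df["strand"]) == ["*"]
        assert list(t.width) == [6]

    @pytest.mark.parametrize("row,match", [
        ({"seqname": "chr1", "start": 10, "end": 5, "strand": "+"}, "start > end"),
        ({"seqname": "chr1", "start": 0, "end": 5}, "start < 1"),
        ({"seqname": "chr1", "start": 1, "end": 5, "strand": "x"}, "strand"),
    ])
    def test_invariant_violations(self, row, match):
        with pytest.raises(RangeValidationError, match=match):
            rt([row])

    def test_end_beyond_declared_length(self):
        g = pg.GenomeInfo("toy", {"chr1": 100})
        with pytest.raises(RangeValidationError, match="exceeds"):
            rt([{"seqname": "chr1", "start": 90, "end": 101}], genome=g)

    def test_three_rows_in_three_out(self):
        rows = [{"seqname": "chr1", "start": s, "end": s + 4, "strand": "+"}
                for s in (1, 10, 100)]
        t = rt(rows)
        assert len(t) == 3
        assert list(t.df["start"]) == [1, 10, 100]


class TestGenomeLabel:
    def test_attach_and_idempotent(self):
        t = rt([{"seqname": "chr1", "start": 1, "end": 2}])
        t2 = pg.with_genome(t, "hg38")
        assert t2.genome.label == "hg38"
        assert pg.with_genome(t2, "hg38").genome.label == "hg38"

    def test_relabel_requires_force(self):
        t = pg.with_genome(rt([{"seqname": "chr1", "start": 1, "end": 2}]),
                           "GRCh38")
        with pytest.raises(GenomeMismatchError):
            pg.with_genome(t, "hg38")
        assert pg.with_genome(t, "hg38", force=True).genome.label == "hg38"

    def test_empty_label_rejected(self):
        t = rt([{"seqname": "chr1", "start": 1, "end": 2}])
        with pytest.raises(RangeValidationError):
            pg.with_genome(t, "")


class TestRestyleSeqnames:
    @pytest.mark.parametrize("name,expected", [
        ("1", "chr1"), ("MT", "chrM"), ("chr1", "chr1"), ("X", "chrX"),
    ])
    def test_ucsc_mapping(self, name, expected):
        t = rt([{"seqname": name, "start": 1, "end": 2}])
        assert pg.restyle_seqnames(t, "UCSC").df["seqname"][0] == expected

    def test_roundtrip_and_unmapped_warns(self):
        t = rt([{"seqname": "22", "start": 1, "end": 2},
                {"seqname": "scaffold_7", "start": 1, "end": 2}])
        with pytest.warns(UserWarning, match="scaffold_7"):
            u = pg.restyle_seqnames(t, "UCSC")
        assert list(u.df["seqname"]) == ["chr22", "scaffold_7"]
        with pytest.warns(UserWarning):
            back = pg.restyle_seqnames(u, "Ensembl")
        assert list(back.df["seqname"]) == ["22", "scaffold_7"]


class TestAnchoredSetWidth:
    def test_five_prime_width_one_is_tss(self):
        t = rt([{"seqname": "chr1", "start": 196651878, "end": 196747504,
                 "strand": "+"}])
        out = pg.anchored_set_width(t, "five_prime", 1)
        assert (out.df["start"][0], out.df["end"][0]) == (196651878, 196651878)

    @pytest.mark.parametrize("seqname,start,end,strand,w_start,w_end", [
        ("chr1", 196651878, 196747504, "+", 196641878, 196661877),
        ("chr6", 46129993, 46146699, "+", 46119993, 46139992),
        ("chr17", 43527844, 43579620, "-", 43569620, 43589619),
        ("chr20", 63895182, 63936031, "+", 63885182, 63905181),
    ])
    def test_printed_promoter_windows(self, seqname, start, end, strand,
                                      w_start, w_end):
        """5'-anchor to width 1 then center-anchor to width 20000 reproduces
        the four printed windows exactly."""
        t = rt([{"seqname": seqname, "start": start, "end": end,
                 "strand": strand}])
        out = pg.anchored_set_width(
            pg.anchored_set_width(t, "five_prime", 1), "center", 20_000)
        assert (out.df["start"][0], out.df["end"][0]) == (w_start, w_end)

    def test_center_floor_toward_minus_inf(self):
        # width 1 -> 4: floor((1-4)/2) = -2, so [10,10] -> [8,11]
        t = rt([{"seqname": "c", "start": 10, "end": 10}])
        out = pg.anchored_set_width(t, "center", 4)
        assert (out.df["start"][0], out.df["end"][0]) == (8, 11)

    @given(start=st.integers(1000, 5000), width=st.integers(1, 400),
           new_width=st.integers(1, 400))
    def test_center_identity_brute_enumeration(self, start, width, new_width):
        """Centering satisfies the midpoint identity: the new midpoint differs
        from the old by at most half a base of parity slack."""
        t = rt([{"seqname": "c", "start": start, "end": start + width - 1}])
        out = pg.anchored_set_width(t, "center", new_width)
        s2, e2 = int(out.df["start"][0]), int(out.df["end"][0])
        assert e2 - s2 + 1 == new_width
        old_mid2 = 2 * start + width - 1   # 2 * midpoint
        new_mid2 = s2 + e2
        assert abs(new_mid2 - old_mid2) <= 1

    @given(st.integers(1, 50), st.integers(1, 50), st.booleans())
    def test_strand_flip_swaps_five_and_three_prime(self, width, new_width,
                                                    plus):
        strand, flipped = ("+", "-") if plus else ("-", "+")
        t = rt([{"seqname": "c", "start": 100, "end": 100 + width - 1,
                 "strand": strand}])
        f = rt([{"seqname": "c", "start": 100, "end": 100 + width - 1,
                 "strand": flipped}])
        five = pg.anchored_set_width(t, "five_prime", new_width)
        three_on_flip = pg.anchored_set_width(f, "three_prime", new_width)
        assert five.df[["start", "end"]].equals(
            three_on_flip.df[["start", "end"]])

    def test_unstranded_anchors_like_plus(self):
        star = rt([{"seqname": "c", "start": 10, "end": 20}])
        plus = rt([{"seqname": "c", "start": 10, "end": 20, "strand": "+"}])
        for anchor in ("five_prime", "three_prime"):
            a = pg.anchored_set_width(star, anchor, 3).df
            b = pg.anchored_set_width(plus, anchor, 3).df
            assert a[["start", "end"]].equals(b[["start", "end"]])

    def test_start_below_one_errors(self):
        t = rt([{"seqname": "c", "start": 3, "end": 3}])
        with pytest.raises(RangeValidationError, match="below 1"):
            pg.anchored_set_width(t, "center", 100)


class TestBindRanges:
    def test_names_and_order(self):
        a = rt([{"seqname": "c", "start": 1, "end": 2}] * 2)
        b = rt([{"seqname": "c", "start": 5, "end": 6}] * 3)
        out = pg.bind_ranges({"a": a, "b": b}, id_column="src")
        assert list(out.df["src"]) == ["a", "a", "b", "b", "b"]

    def test_universe_size_identity(self):
        de = rt([{"seqname": "c", "start": i + 1, "end": i + 2}
                 for i in range(749)])
        parts = {"de": de}
        for i in range(10):
            parts[f"r{i}"] = de
        out = pg.bind_ranges(parts, id_column="resample")
        assert len(out) == 8239

    def test_missing_columns_filled(self):
        a = rt([{"seqname": "c", "start": 1, "end": 2, "x": 1.0}])
        b = rt([{"seqname": "c", "start": 5, "end": 6}])
        out = pg.bind_ranges({"a": a, "b": b}, id_column="src")
        assert out.df["x"].isna().tolist() == [False, True]

    def test_conflicting_genomes_error(self):
        a = pg.with_genome(rt([{"seqname": "c", "start": 1, "end": 2}]), "hg38")
        b = pg.with_genome(rt([{"seqname": "c", "start": 1, "end": 2}]), "mm10")
        with pytest.raises(GenomeMismatchError):
            pg.bind_ranges({"a": a, "b": b}, id_column="src")


class TestJoinOverlapLeft:
    def test_no_overlap_emits_single_na_row(self):
        left = rt([{"seqname": "chr1", "start": 1, "end": 10}])
        right = rt([{"seqname": "chr2", "start": 1, "end": 10, "id": "p"}])
        out = pg.join_overlap_left(left, right)
        assert len(out) == 1
        assert out.df["id"].isna().all()
        assert out.df["start"][0] == 1  # left coordinates kept

    def test_enumerated_pairs(self):
        left = rt([{"seqname": "chr1", "start": 1, "end": 10},
                   {"seqname": "chr1", "start": 20, "end": 30}])
        right = rt([{"seqname": "chr1", "start": 5, "end": 6, "id": "a"},
                    {"seqname": "chr1", "start": 8, "end": 25, "id": "b"},
                    {"seqname": "chr1", "start": 40, "end": 50, "id": "c"}])
        out = pg.join_overlap_left(left, right)
        pairs = list(zip(out.df["start"], out.df["id"]))
        assert pairs == [(1, "a"), (1, "b"), (20, "b")]

    def test_collision_suffix_and_strand_kept(self):
        left = rt([{"seqname": "c", "start": 1, "end": 10, "strand": "-",
                    "score": 1.0}])
        right = rt([{"seqname": "c", "start": 5, "end": 6, "score": 2.0}])
        out = pg.join_overlap_left(left, right)
        assert out.df["score"][0] == 1.0
        assert out.df["score.y"][0] == 2.0
        assert out.df["strand"][0] == "-"

    def test_genome_mismatch_is_hard_error(self):
        left = pg.with_genome(rt([{"seqname": "c", "start": 1, "end": 2}]),
                              "hg38")
        right = pg.with_genome(rt([{"seqname": "c", "start": 1, "end": 2}]),
                               "GRCh38")
        with pytest.raises(GenomeMismatchError):
            pg.join_overlap_left(left, right)

    def test_one_unset_genome_warns(self):
        left = pg.with_genome(rt([{"seqname": "c", "start": 1, "end": 2}]),
                              "hg38")
        right = rt([{"seqname": "c", "start": 1, "end": 2}])
        with pytest.warns(UserWarning, match="unlabeled"):
            pg.join_overlap_left(left, right)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 200, size=2)
        left = rt(_random_intervals(rng, n, meta="L"))
        right = rt(_random_intervals(rng, m, meta="R"))
        out = pg.join_overlap_left(left, right)
        expected = brute_join(records(left.df), records(right.df), ["R"])
        assert len(out) == len(expected)
        got = records(out.df)
        for g, e in zip(got, expected):
            assert g["seqname"] == e["seqname"]
            assert g["start"] == e["start"] and g["end"] == e["end"]
            assert g["R"] == e["R"]
        # row-count identity: sum over left of max(1, overlaps)
        per_left = [
            sum(1 for r in records(right.df)
                if r["seqname"] == l["seqname"]
                and r["start"] <= l["end"] and l["start"] <= r["end"])
            for l in records(left.df)]
        assert len(out) == sum(max(1, k) for k in per_left)

    def test_same_strand_mode(self):
        left = rt([{"seqname": "c", "start": 1, "end": 10, "strand": "+"}])
        right = rt([{"seqname": "c", "start": 5, "end": 6, "strand": "-",
                     "id": "x"}])
        out = pg.join_overlap_left(left, right, same_strand=True)
        assert out.df["id"].isna().all()

    def test_cross_check_against_pyranges(self):
        """Independent route: pyranges overlap join on the same instance."""
        pr = pytest.importorskip("pyranges")
        rng = np.random.default_rng(7)
        left = rt(_random_intervals(rng, 80, meta="L"))
        right = rt(_random_intervals(rng, 120, meta="R"))
        out = pg.join_overlap_left(left, right)
        matched = int(out.df["R"].notna().sum())

        def to_pr(t):
            return pr.PyRanges(pd.DataFrame({
                "Chromosome": t.df["seqname"],
                "Start": t.df["start"] - 1,  # closed -> half-open
                "End": t.df["end"],
            }))

        joined = to_pr(left).join(to_pr(right))
        assert len(joined) == matched


def _random_intervals(rng, n, meta):
    start = rng.integers(1, 500, size=n)
    return pd.DataFrame({
        "seqname": rng.choice(["chr1", "chr2"], size=n),
        "start": start,
        "end": start + rng.integers(0, 60, size=n),
        "strand": rng.choice(["+", "-", "*"], size=n),
        meta: rng.normal(size=n),
    })


class TestReduceRangesDirected:
    def test_identical_ranges_collapse_and_count(self):
        t = rt([{"seqname": "c", "start": 1, "end": 5, "strand": "+",
                 "g": "a", "x": v} for v in (1.0, 2.0, np.nan, 3.0)])
        out = pg.reduce_ranges_directed(
            t, ["g"], {"n": agg.count_non_missing("x")})
        assert len(out) == 1
        assert out.df["n"][0] == 3

    @pytest.mark.parametrize("s2,e2,n_rows", [
        (4, 10, 1),   # overlapping
        (6, 10, 1),   # book-ended (gap 0)
        (7, 10, 2),   # gap 1: not merged
    ])
    def test_merge_rules(self, s2, e2, n_rows):
        t = rt([{"seqname": "c", "start": 1, "end": 5, "strand": "+", "g": "a"},
                {"seqname": "c", "start": s2, "end": e2, "strand": "+",
                 "g": "a"}])
        out = pg.reduce_ranges_directed(t, ["g"], {})
        assert len(out) == n_rows
        if n_rows == 1:
            assert (out.df["start"][0], out.df["end"][0]) == (1, 10)

    def test_directed_means_strands_do_not_merge(self):
        t = rt([{"seqname": "c", "start": 1, "end": 5, "strand": "+", "g": "a"},
                {"seqname": "c", "start": 4, "end": 10, "strand": "-",
                 "g": "a"}])
        out = pg.reduce_ranges_directed(t, ["g"], {})
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        start = rng.integers(1, 100, size=n)
        t = rt(pd.DataFrame({"seqname": "c", "start": start,
                             "end": start + rng.integers(0, 20, size=n),
                             "strand": "+", "g": "a"}))
        out = pg.reduce_ranges_directed(t, ["g"], {})
        got = list(zip(out.df["start"], out.df["end"]))
        expected = brute_merge(zip(t.df["start"], t.df["end"]))
        assert sorted(got) == expected

    def test_row_order_invariance(self, rng):
        df = _random_intervals(rng, 40, meta="x")
        df["g"] = rng.choice(["a", "b"], size=len(df))
        t1 = rt(df)
        t2 = rt(df.sample(frac=1, random_state=3))
        aggs = {"s": agg.sum_("x"), "m": agg.max_abs("x")}
        r1 = pg.reduce_ranges_directed(t1, ["g"], aggs)
        r2 = pg.reduce_ranges_directed(t2, ["g"], aggs)
        key = ["g", "seqname", "strand", "start"]
        a = r1.df.sort_values(key).reset_index(drop=True)
        b = r2.df.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_aggregator_and_absent_column(self):
        t = rt([{"seqname": "c", "start": 1, "end": 2, "g": "a"}])
        with pytest.raises(AggregatorError, match="unknown aggregator"):
            pg.reduce_ranges_directed(t, ["g"], {"bad": len})
        with pytest.raises(AggregatorError, match="absent column"):
            pg.reduce_ranges_directed(t, ["g"], {"s": agg.sum_("nope")})


class TestExpandListColumns:
    def test_lengthens_and_repeats_scalars(self):
        t = rt([{"seqname": "c", "start": 1, "end": 2, "g": "a",
                 "v": [1, 2, 3], "t": [0.1, 0.2, 0.3]}])
        out = pg.expand_list_columns(t, ["v", "t"])
        assert len(out) == 3
        assert list(out.df["g"]) == ["a"] * 3
        assert list(out.df["v"]) == [1, 2, 3]

    def test_length_mismatch_errors(self):
        t = rt([{"seqname": "c", "start": 1, "end": 2,
                 "v": [1, 2, 3], "t": [0.1, 0.2]}])
        with pytest.raises(RangeValidationError, match="length mismatch"):
            pg.expand_list_columns(t, ["v", "t"])

    def test_total_length_arithmetic(self, rng):
        n, k = 50, 7
        t = rt(pd.DataFrame({
            "seqname": "c", "start": np.arange(1, n + 1),
            "end": np.arange(2, n + 2),
            "v": [list(range(k)) for _ in range(n)],
        }))
        assert len(pg.expand_list_columns(t, ["v"])) == n * k

    def test_expand_then_collect_is_identity(self, rng):
        rows = []
        for i in range(10):
            k = int(rng.integers(1, 6))
            rows.append({"seqname": "c", "start": i + 1, "end": i + 1,
                         "rowid": i, "v": list(rng.integers(0, 9, size=k))})
        t = rt(pd.DataFrame(rows))
        expanded = pg.expand_list_columns(t, ["v"])
        back = pg.reduce_ranges_directed(
            expanded, ["rowid"], {"v": agg.collect_list("v")})
        assert [list(v) for v in back.df["v"]] == [r["v"] for r in rows]


class TestSummarizeGroups:
    def test_n_distinct_and_missing_drop(self):
        t = rt([{"seqname": "c", "start": 1, "end": 2, "origin": "de",
                 "resample": r, "x": x}
                for r, x in [(1, 1.0), (1, 2.0), (2, np.nan)]])
        out = pg.summarize_groups(t, ["origin"], {
            "nd": agg.n_distinct("resample"),
            "s": agg.sum_("x"),
        })
        assert out["nd"][0] == 2
        assert out["s"][0] == 3.0

    def test_ratio_matches_hand_count(self):
        rows = []
        for resample, n_obs in [(1, 3), (2, 1), (3, 2)]:
            for i in range(n_obs):
                rows.append({"seqname": "c", "start": 1, "end": 2,
                             "origin": "not_de", "resample": resample,
                             "da_padj": 0.001})
        rows.append({"seqname": "c", "start": 1, "end": 2, "origin": "not_de",
                     "resample": 3, "da_padj": np.nan})
        t = rt(pd.DataFrame(rows))
        out = pg.summarize_groups(t, ["origin"], {
            "peak_count": agg.Ratio(agg.count_non_missing("da_padj"),
                                    agg.n_distinct("resample"))})
        assert out["peak_count"][0] == 6 / 3


class TestSliceSample:
    def test_sizes_and_distinctness(self, rng):
        t = rt(_random_intervals(rng, 30, meta="x"))
        out = pg.slice_sample(t, 10, rng)
        assert len(out) == 10
        assert not out.df["x"].duplicated().any()
        assert len(pg.slice_sample(t, 0, rng)) == 0
        assert list(pg.slice_sample(t, 0, rng).df.columns) == list(t.df.columns)

    def test_full_size_is_permutation(self, rng):
        t = rt(_random_intervals(rng, 15, meta="x"))
        out = pg.slice_sample(t, 15, rng)
        assert sorted(out.df["x"]) == sorted(t.df["x"])

    def test_oversize_errors(self, rng):
        t = rt(_random_intervals(rng, 5, meta="x"))
        with pytest.raises(ValueError):
            pg.slice_sample(t, 6, rng)
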