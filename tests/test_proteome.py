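"""Hit filtering, %NSAF normalization and category/transport summaries."""

import numpy as np
import pandas as pd
import pytest

from phycotad.io import BLAST6_COLUMNS, read_hits
from phycotad.niche import NicheLabels
from phycotad.proteome import (NSAFTable, ProteinAnnotationTable,
                               SpectralCounts, cobalamin_summary,
                               compute_nsaf, filter_hits, load_ko_flags,
                               top_categories, transport_share)
from phycotad.synthetic_data import SimConfig, generate_dataset


def _hits(rows):
    """rows of (protein, subject, pident, evalue)"""
    out = []
    for q, s, pid, ev in rows:
        out.append((q, s, pid, 100, 0, 0, 1, 100, 1, 100, ev, 200.0))
    return pd.DataFrame(out, columns=BLAST6_COLUMNS)


class TestFilterHits:
    def test_passing_hit_assigned(self):
        res = filter_hits(_hits([("p1", "magA|c1", 99.5, 1e-20)]))
        assert res.assignments.to_dict() == {"p1": "magA"}

    def test_identity_at_or_below_threshold_fails(self):
        res = filter_hits(_hits([("p1", "magA|c1", 98.0, 1e-30),
                                 ("p2", "magB|c1", 99.0, 1e-30)]))
        assert res.assignments.empty
        assert res.unassigned == ["p1", "p2"]

    def test_evalue_at_threshold_fails(self):
        res = filter_hits(_hits([("p1", "magA|c1", 99.5, 1e-10)]))
        assert res.assignments.empty

    def test_two_mags_excluded_as_ambiguous(self):
        res = filter_hits(_hits([("p1", "magA|c1", 99.5, 1e-20),
                                 ("p1", "magB|c1", 99.5, 1e-20)]))
        assert res.ambiguous == ["p1"]
        assert res.assignments.empty

    def test_two_contigs_same_mag_kept(self):
        res = filter_hits(_hits([("p1", "magA|c1", 99.5, 1e-20),
                                 ("p1", "magA|c2", 99.8, 1e-25)]))
        assert res.assignments.to_dict() == {"p1": "magA"}

    def test_order_independent_and_idempotent(self):
        rows = [("p1", "magA|c1", 99.5, 1e-20),
                ("p2", "magB|c1", 99.9, 1e-30),
                ("p2", "magC|c1", 99.9, 1e-30),
                ("p3", "magA|c2", 98.5, 1e-30)]
        a = filter_hits(_hits(rows))
        b = filter_hits(_hits(rows[::-1]))
        assert a.assignments.equals(b.assignments)
        assert a.ambiguous == b.ambiguous == ["p2"]

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("p1\tmagA|c1\t99.5\t100\t0\t0\t1\t100\t1\t100\t"
                        "1e-20\t200\np2\tmagB\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            read_hits(path)


class TestNSAF:
    def test_single_protein_is_100(self):
        sc = SpectralCounts(pd.DataFrame({"s1": [12]}, index=["p1"]),
                            pd.Series({"p1": 300}))
        assert compute_nsaf(sc).values.iloc[0, 0] == pytest.approx(100.0)

    def test_length_normalization(self):
        sc = SpectralCounts(
            pd.DataFrame({"s1": [10, 10]}, index=["p1", "p2"]),
            pd.Series({"p1": 100, "p2": 200}))
        vals = compute_nsaf(sc).values["s1"]
        assert vals.tolist() == pytest.approx([200 / 3, 100 / 3])

    def test_samples_sum_to_100(self, dataset):
        nsaf = compute_nsaf(dataset.spectral_counts)
        sums = nsaf.values.sum(axis=0)
        assert np.abs(sums - 100.0).max() < 1e-9

    def test_empty_sample_flagged(self):
        sc = SpectralCounts(
            pd.DataFrame({"s1": [5], "s2": [0]}, index=["p1"]),
            pd.Series({"p1": 100}))
        nsaf = compute_nsaf(sc)
        assert nsaf.flagged_samples == ["s2"]
        assert np.isnan(nsaf.values.loc["p1", "s2"])


def _nsaf(values, assigned, anno_rows):
    nsaf = NSAFTable(pd.DataFrame(values),
                     pd.Series(assigned, dtype=object))
    anno = ProteinAnnotationTable(
        pd.DataFrame(anno_rows, columns=["protein_id", "ko_id", "brite"]
                     ).set_index("protein_id"))
    return nsaf, anno


class TestCategories:
    def test_single_category_is_rank_one(self):
        nsaf, anno = _nsaf({"s1": {"p1": 100.0}}, {"p1": "magA"},
                           [("p1", "K00001", "Ribosome")])
        top, _ = top_categories(nsaf, anno)
        assert top == ["Ribosome"]

    def test_tie_breaks_lexicographically(self):
        nsaf, anno = _nsaf({"s1": {"p1": 60.0, "p2": 40.0}},
                           {"p1": "magA", "p2": "magA"},
                           [("p1", "K1", "Zeta"), ("p2", "K2", "Alpha")])
        top, _ = top_categories(nsaf, anno, k=2)
        assert top == ["Alpha", "Zeta"]

    def test_transport_among_top_on_synthetic(self, dataset):
        from phycotad.proteome import filter_hits as fh
        assign = fh(dataset.hits).assignments
        nsaf = compute_nsaf(dataset.spectral_counts, assign)
        anno = ProteinAnnotationTable(dataset.protein_anno)
        top, cells = top_categories(nsaf, anno, k=10)
        assert "Transporters" in top
        # sum-then-log: cells carry log10 of summed %NSAF
        pos = cells[cells["summed_pct_nsaf"] > 0]
        assert np.allclose(pos["log10_summed_pct_nsaf"],
                           np.log10(pos["summed_pct_nsaf"]))


class TestCobalamin:
    def test_not_detected_group_reported(self):
        nsaf, anno = _nsaf({"s1": {"p1": 100.0}}, {"p1": "magA"},
                           [("p1", "K00798", "Porphyrin")])
        groups = pd.Series({"magA": "Rhodobacterales",
                            "magB": "Flavobacteriales"})
        out = cobalamin_summary(nsaf, anno, groups)
        flavo = out[(out["group"] == "Flavobacteriales")]
        assert (~flavo["detected"]).all()
        rhodo_bio = out[(out["group"] == "Rhodobacterales")
                        & (out["category"] == "biosynthesis")].iloc[0]
        assert rhodo_bio["detected"]
        assert rhodo_bio["n_proteins"] == 1
        assert rhodo_bio["summed_pct_nsaf"] == pytest.approx(100.0)

    def test_synthetic_biosynthesis_only_from_rhodobacterales(self, dataset):
        anno = ProteinAnnotationTable(dataset.protein_anno)
        bio = anno.proteins_with_flag("cobalamin_biosynthesis")
        assert len(bio) == 4
        # all simulated MAGs are Rhodobacterales; every marker maps to one
        assert set(dataset.truth.protein_mag[bio]) <= \
            set(dataset.truth.labels.index)


class TestTransportShare:
    def _labels(self, mapping):
        s = pd.Series(mapping)
        return NicheLabels(s, pd.Series("NO_SIG", index=s.index))

    def test_all_generalist_is_one(self):
        nsaf, anno = _nsaf({"s1": {"p1": 100.0}}, {"p1": "magA"},
                           [("p1", "K02025", "Transporters")])
        res = transport_share(nsaf, anno, self._labels({"magA": "generalist"}))
        assert res.share == pytest.approx(1.0)

    def test_equal_split_is_half(self):
        nsaf, anno = _nsaf({"s1": {"p1": 50.0, "p2": 50.0}},
                           {"p1": "magA", "p2": "magB"},
                           [("p1", "K02025", "Transporters"),
                            ("p2", "K02026", "Transporters")])
        res = transport_share(nsaf, anno, self._labels(
            {"magA": "generalist", "magB": "colonizer"}))
        assert res.share == pytest.approx(0.5)
        assert res.denominator == pytest.approx(100.0)

    def test_share_tracks_generator_parameter(self, niche_labels, dataset):
        """Mean estimated share over seeds stays near the planted 0.85."""
        shares = []
        for seed in range(5):
            ds = generate_dataset(SimConfig(seed=seed))
            assign = filter_hits(ds.hits).assignments
            nsaf = compute_nsaf(ds.spectral_counts, assign)
            anno = ProteinAnnotationTable(ds.protein_anno)
            labels = NicheLabels(ds.truth.labels,
                                 pd.Series("NO_SIG",
                                           index=ds.truth.labels.index))
            shares.append(transport_share(nsaf, anno, labels).share)
        assert abs(np.mean(shares) - 0.85) < 0.05


def test_ko_flag_map_loads_and_validates():
    flags = load_ko_flags()
    assert "transport" in flags["K02025"]
    assert "cobalamin_biosynthesis" in flags["K00798"]
    assert "cobalamin_biosynthesis" in flags["K02234"]
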