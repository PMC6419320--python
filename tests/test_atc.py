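"""ATC frequency matrix, filtering, and two-way hierarchical clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import labelsafe as ls
from labelsafe.atc import AtcError, _linkage_labels
from labelsafe.occurrence import SECTIONS, DrugPTMatrix

from test_occurrence import matrix_from_plants


def block_setup(seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    return ls.sample_block_matrix(rng, **kwargs)


class TestBuildAtcPtMatrix:
    def test_sparse_classes_filtered(self):
        m, atc, _ = block_setup(drugs_per_atc=6)
        # shrink two classes below the threshold
        small = {"L01", "L02"}
        atc2 = ls.ATCMap(entries={
            sid: codes for sid, codes in atc.entries.items()
            if not (codes & small) or sid.endswith(("00", "01"))
        })
        keep = {sid for sid in m.set_ids if sid in atc2.entries}
        ci = ls.build_atc_pt_matrix(m, ls.ATCMap(entries={
            sid: atc2.entries[sid] for sid in keep
        }), min_drugs=5)
        assert small.isdisjoint(ci.matrix.columns)
        assert ci.filters_applied["atc_columns_dropped"] == 2

    def test_zero_count_transforms_to_zero(self):
        m, atc, _ = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        raw = ci.raw_counts.to_numpy()
        assert ci.matrix.to_numpy()[np.isclose(raw, 0)].sum() == 0.0

    def test_multi_atc_drug_counts_in_both_classes(self):
        plants = {f"D{i}": {"BW": {1}} for i in range(10)}
        m = matrix_from_plants(plants, [1, 2])
        atc = ls.ATCMap(entries={
            f"D{i}": ({"A01", "B01"} if i < 5 else {"A01"}) for i in range(10)
        })
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        raw = ci.raw_counts
        assert raw.loc[ci.matrix.index[0], "A01"] == pytest.approx(10)
        assert raw.loc[ci.matrix.index[0], "B01"] == pytest.approx(5)

    def test_filters_use_raw_counts_not_transformed(self):
        # a PT in 4 drugs survives at min_drugs=4 but not 5, regardless of
        # the log2 values involved
        plants = {f"D{i}": {"BW": {1} | ({2} if i < 4 else set())}
                  for i in range(6)}
        m = matrix_from_plants(plants, [1, 2])
        atc = ls.ATCMap(entries={f"D{i}": {"A01"} for i in range(6)})
        ci4 = ls.build_atc_pt_matrix(m, atc, min_drugs=4)
        ci5 = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        assert ci4.matrix.shape[0] == 2
        assert ci5.matrix.shape[0] == 1

    def test_empty_after_filtering_raises_with_counts(self):
        plants = {"D0": {"BW": {1}}}
        m = matrix_from_plants(plants, [1])
        atc = ls.ATCMap(entries={"D0": {"A01"}})
        with pytest.raises(AtcError, match="min_drugs"):
            ls.build_atc_pt_matrix(m, atc, min_drugs=5)

    def test_invalid_atc_code_rejected(self):
        with pytest.raises(AtcError):
            ls.ATCMap(entries={"D0": {"L1"}})

    def test_atc_tsv_round_trip(self, tmp_path):
        _, atc, _ = block_setup()
        path = tmp_path / "atc.tsv"
        ls.write_atc_tsv(atc, str(path))
        back = ls.read_atc_tsv(str(path))
        assert back.entries == atc.entries


class TestTwoWayHca:
    def test_identical_columns_merge_first_at_height_zero(self):
        plants = {f"D{i}": {"BW": {1, 2}} for i in range(12)}
        m = matrix_from_plants(plants, [1, 2, 3])
        atc = ls.ATCMap(entries={
            f"D{i}": {("A01", "B01", "C01")[i % 3]} for i in range(12)
        })
        # A01 and B01 get identical profiles by construction
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=1)
        hca = ls.two_way_hca(ci)
        first = hca.col_linkage[0]
        assert first[2] == 0.0

    def test_planted_two_block_partition_recovered(self):
        for seed in range(5):
            m, atc, partition = block_setup(seed=seed)
            ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
            hca = ls.two_way_hca(ci)
            rep = ls.cluster_report(ci, hca, n_clusters=2)
            assign = {c: r["cluster"] for r in rep for c in r["atc_members"]}
            cols = sorted(assign)
            ari = adjusted_rand_score(
                [partition[c] for c in cols], [assign[c] for c in cols]
            )
            assert ari == 1.0

    def test_block_pair_mutual_nearest_neighbors(self):
        # two classes sharing a large PT set distinct from all others merge
        # before either joins anything else
        m, atc, partition = block_setup(n_blocks=3, atcs_per_block=2)
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        cols = _linkage_labels(hca)
        first_merge = hca.col_linkage[0]
        pair = {cols[int(first_merge[0])], cols[int(first_merge[1])]}
        blocks = {partition[c] for c in pair}
        assert len(blocks) == 1  # first merge joins same-block classes

    def test_label_equivariance_under_permutation(self):
        m, atc, _ = block_setup(seed=3)
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        ci_perm = ls.ClusterInput(
            matrix=ci.matrix.iloc[::-1, ::-1],
            pt_codes=list(reversed(ci.pt_codes)),
        )
        hca_perm = ls.two_way_hca(ci_perm)
        assert set(hca.col_order) == set(hca_perm.col_order)
        # same tree: merge heights identical
        np.testing.assert_allclose(
            sorted(hca.col_linkage[:, 2]), sorted(hca_perm.col_linkage[:, 2])
        )

    def test_merge_heights_monotone(self):
        m, atc, _ = block_setup(seed=4)
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        for Z in (hca.row_linkage, hca.col_linkage):
            assert (np.diff(Z[:, 2]) >= 0).all()

    def test_newick_output_parses(self):
        import dendropy

        m, atc, _ = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        tree = dendropy.Tree.get(data=hca.col_newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(ci.matrix.columns)

    def test_too_small_matrix_raises(self):
        plants = {"D0": {"BW": {1}}}
        m = matrix_from_plants(plants, [1])
        atc = ls.ATCMap(entries={"D0": {"A01"}})
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=1)
        with pytest.raises(AtcError):
            ls.two_way_hca(ci)


class TestClusterReport:
    def test_planted_block_pts_reported_enriched(self):
        m, atc, partition = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        rep = ls.cluster_report(ci, hca, n_clusters=2, margin=0.5)
        # each cluster's enriched PTs are exactly its block's planted PTs
        for entry in rep:
            blocks = {partition[c] for c in entry["atc_members"]}
            assert len(blocks) == 1
            assert len(entry["enriched_pts"]) > 0

    def test_single_cluster_cut_has_no_enrichment(self):
        m, atc, _ = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        rep = ls.cluster_report(ci, hca, n_clusters=1, margin=0.0)
        assert len(rep) == 1
        assert rep[0]["enriched_pts"] == []

    def test_infinite_margin_empties_enrichment(self):
        m, atc, _ = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        rep = ls.cluster_report(ci, hca, n_clusters=2, margin=float("inf"))
        assert all(r["enriched_pts"] == [] for r in rep)

    def test_cut_height_outside_range_raises(self):
        m, atc, _ = block_setup()
        ci = ls.build_atc_pt_matrix(m, atc, min_drugs=5)
        hca = ls.two_way_hca(ci)
        with pytest.raises(ValueError):
            ls.cluster_report(ci, hca, cut_height=1e9)
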