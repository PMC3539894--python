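import numpy as np
import pandas as pd
import pytest

from noiseplast.neighborhood import (ARCHITECTURE_LABELS, annotate_neighborhood,
                                     apply_neighborhood_filters,
                                     architecture_label, architecture_summary,
                                     find_upstream_partner,
                                     intergenic_distance)


def transcripts(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "kind", "chrom",
                                       "strand", "tss", "tes", "status",
                                       "bipromoter"])


def row(df, tid):
    return next(t for t in df.itertuples(index=False)
                if t.transcript_id == tid)


class TestFindUpstreamPartner:
    def test_divergent_partner(self, tiny_transcripts):
        focal = row(tiny_transcripts, "g1")
        cands = tiny_transcripts.query("chrom == 'chrA' and transcript_id != 'g1'")
        hit = find_upstream_partner(focal, cands)
        assert hit.partner_id == "p1" and hit.orientation == "divergent"

    def test_parallel_partner(self, tiny_transcripts):
        focal = row(tiny_transcripts, "g2")
        cands = tiny_transcripts.query("chrom == 'chrA' and transcript_id != 'g2'")
        hit = find_upstream_partner(focal, cands)
        assert hit.partner_id == "g1" and hit.orientation == "parallel"

    def test_nearest_facing_edge_wins(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("far", "ORF_T", "c", "-", 4500, 4000, "verified", False),
            ("near", "ORF_T", "c", "-", 4800, 4600, "verified", False)])
        hit = find_upstream_partner(row(ts, "f"), ts[ts.transcript_id != "f"])
        assert hit.partner_id == "near"

    def test_no_candidates_none(self, tiny_transcripts):
        focal = row(tiny_transcripts, "g1")
        hit = find_upstream_partner(focal, tiny_transcripts.iloc[0:0])
        assert hit.partner_id is None and hit.orientation == "none"

    def test_overlapping_nearest_flagged(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("ov", "ORF_T", "c", "+", 4500, 5100, "verified", False)])
        hit = find_upstream_partner(row(ts, "f"), ts[ts.transcript_id != "f"])
        assert hit.partner_id == "ov" and hit.overlap


class TestIntergenicDistance:
    def test_divergent_tss_to_tss(self, tiny_transcripts):
        assert intergenic_distance(row(tiny_transcripts, "g1"),
                                   row(tiny_transcripts, "p1")) == 200

    def test_parallel_tss_to_tes(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("p", "ORF_T", "c", "+", 4000, 4950, "verified", False)])
        assert intergenic_distance(row(ts, "f"), row(ts, "p")) == 50

    def test_minus_strand_mirror(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "-", 1000, 500, "verified", False),
            ("p", "ORF_T", "c", "+", 1300, 1700, "verified", False)])
        assert intergenic_distance(row(ts, "f"), row(ts, "p")) == 300

    def test_overlap_is_error(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("p", "ORF_T", "c", "+", 4000, 5200, "verified", False)])
        with pytest.raises(ValueError, match="overlap"):
            intergenic_distance(row(ts, "f"), row(ts, "p"))


class TestArchitectureLabel:
    @pytest.mark.parametrize("orient,kind,bip,expected", [
        ("divergent", "ORF_T", True, "bipromoter_C"),
        ("divergent", "SUT", False, "divergent_NC"),
        ("divergent", "CUT", True, "bipromoter_NC"),
        ("parallel", "ORF_T", False, "parallel_C"),
    ])
    def test_mapping(self, orient, kind, bip, expected):
        assert architecture_label(orient, kind, bip) == expected

    def test_parallel_bipromoter_is_inconsistent(self):
        with pytest.raises(ValueError):
            architecture_label("parallel", "ORF_T", True)


class TestFiltersAndAnnotation:
    def test_dubious_partner_excluded(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("d", "ORF_T", "c", "-", 4800, 4400, "dubious", False)])
        ann = annotate_neighborhood(ts)
        r = ann.set_index("gene_id").loc["f"]
        assert r["excluded"] and r["exclude_reason"] == "dubious_partner"

    def test_overlap_excluded(self):
        ts = transcripts([
            ("f", "ORF_T", "c", "+", 5000, 6000, "verified", False),
            ("ov", "ORF_T", "c", "+", 4500, 5010, "verified", False)])
        ann = annotate_neighborhood(ts, focal_ids=["f"])
        r = ann.set_index("gene_id").loc["f"]
        assert r["excluded"] and r["exclude_reason"] == "overlap"

    def test_clean_gap_not_excluded(self, tiny_transcripts):
        ann = annotate_neighborhood(tiny_transcripts)
        r = ann.set_index("gene_id").loc["g1"]
        assert not r["excluded"]
        assert r["intergenic_distance"] == 200
        assert r["architecture"] == "divergent_C"

    def test_missing_coords_added_for_unmapped_genes(self, tiny_transcripts):
        genes = pd.DataFrame({"gene_id": ["g1", "ghost"]})
        ann = apply_neighborhood_filters(
            annotate_neighborhood(tiny_transcripts), genes)
        r = ann.set_index("gene_id").loc["ghost"]
        assert r["excluded"] and r["exclude_reason"] == "missing_coords"

    def test_every_non_excluded_gene_has_one_label(self, default_dataset):
        ann = annotate_neighborhood(default_dataset.transcripts)
        live = ann[~ann["excluded"]]
        assert live["architecture"].isin(ARCHITECTURE_LABELS).all()
        assert ann.loc[ann["excluded"], "architecture"].isna().all()

    def test_coordinate_mirror_invariance(self, tiny_transcripts):
        """Reversing the chromosome and flipping strands preserves every
        orientation, distance and label."""
        L = 20_000
        mirrored = tiny_transcripts.copy()
        mirrored["tss"] = L - tiny_transcripts["tss"] + 1
        mirrored["tes"] = L - tiny_transcripts["tes"] + 1
        mirrored["strand"] = tiny_transcripts["strand"].map({"+": "-", "-": "+"})
        a1 = annotate_neighborhood(tiny_transcripts).set_index("gene_id")
        a2 = annotate_neighborhood(mirrored).set_index("gene_id")
        for g in a1.index:
            assert a1.loc[g, "orientation"] == a2.loc[g, "orientation"]
            assert a1.loc[g, "partner_id"] == a2.loc[g, "partner_id"]
            assert a1.loc[g, "intergenic_distance"] == \
                a2.loc[g, "intergenic_distance"]
            assert a1.loc[g, "architecture"] == a2.loc[g, "architecture"]


class TestArchitectureSummary:
    def test_composition_sums_to_100(self, default_dataset, default_classes):
        ann = annotate_neighborhood(default_dataset.transcripts)
        summ = architecture_summary(ann, default_classes,
                                    default_dataset.gene_table)
        np.testing.assert_allclose(summ.composition.sum(axis=1), 100.0)

    def test_single_label_composition(self, default_classes, default_dataset):
        ann = annotate_neighborhood(default_dataset.transcripts)
        one = ann[ann["architecture"] == "parallel_C"]
        summ = architecture_summary(one, default_classes,
                                    default_dataset.gene_table)
        comp = summ.composition
        np.testing.assert_allclose(comp["parallel_C"], 100.0)

    def test_small_label_rho_missing(self, tiny_transcripts):
        genes = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                              "noise_dm": [0.1, 0.2, 0.3],
                              "plasticity": [1.0, 2.0, 3.0]})
        classes = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                                "joint_class": ["HNHP", "LNHP", "other"]})
        ann = annotate_neighborhood(tiny_transcripts)
        summ = architecture_summary(ann, classes, genes)
        # every label with < 4 genes reports a missing correlation
        small = summ.labels[summ.labels["n"] < 4]
        assert len(small) > 0
        assert small["spearman_rho"].isna().all()
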