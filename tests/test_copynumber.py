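"""Segment-to-gene mapping, segment signals, linear scores and cluster calls."""

import numpy as np
import pandas as pd
import pytest

from celtilkit.copynumber import (
    CNModelError,
    CNQualityError,
    CNSignatureModel,
    GeneAnnotation,
    SegmentProfile,
    SegmentRecord,
    assign_cluster,
    map_segments_to_genes,
    score_signatures,
    segment_signal,
)


def _profile(records, sid="S1"):
    return SegmentProfile(sample_id=sid, records=tuple(records))


def _annotation(rows):
    df = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])
    return GeneAnnotation(table=df.set_index("gene"))


class TestGeneMapping:
    def test_gene_inside_one_segment(self):
        p = _profile([SegmentRecord("chr1", 1, 10_000, 0.7)])
        a = _annotation([("g1", "chr1", 100, 200)])
        assert map_segments_to_genes(p, a)["g1"] == pytest.approx(0.7)

    def test_gene_spanning_two_segments_takes_larger_overlap(self):
        # gene 1000..1999: 600 bp in segment A (ends 1599), 400 bp in B
        p = _profile(
            [SegmentRecord("chr1", 1, 1599, 0.2), SegmentRecord("chr1", 1600, 5000, -0.4)]
        )
        a = _annotation([("g1", "chr1", 1000, 1999)])
        assert map_segments_to_genes(p, a)["g1"] == pytest.approx(0.2)

    def test_gene_on_uncovered_chromosome_absent(self):
        p = _profile([SegmentRecord("chr1", 1, 1000, 0.5)])
        a = _annotation([("g1", "chr2", 10, 20), ("g2", "chr1", 100, 200)])
        mapped = map_segments_to_genes(p, a)
        assert "g1" not in mapped.index and "g2" in mapped.index

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            _profile(
                [SegmentRecord("chr1", 1, 1000, 0.0), SegmentRecord("chr1", 900, 2000, 1.0)]
            )


class TestSegmentSignal:
    def test_mean_of_member_genes(self):
        gene_cn = pd.Series({"a": 0.2, "b": 0.4})
        sig = segment_signal(gene_cn, {"seg1": ["a", "b"]})
        assert sig["seg1"] == pytest.approx(0.3)

    def test_constant_members_give_constant(self):
        gene_cn = pd.Series({"a": -0.7, "b": -0.7, "c": -0.7})
        assert segment_signal(gene_cn, {"s": ["a", "b", "c"]})["s"] == pytest.approx(-0.7)

    def test_absent_members_flagged_missing(self):
        gene_cn = pd.Series({"a": 0.1})
        with pytest.warns(UserWarning, match="no signal"):
            sig = segment_signal(gene_cn, {"s1": ["a"], "s2": ["zzz"]})
        assert np.isnan(sig["s2"]) and sig["s1"] == pytest.approx(0.1)

    def test_all_missing_rejected(self):
        with pytest.raises(CNQualityError):
            segment_signal(pd.Series(dtype=float), {"s1": ["a"]})


def _toy_model(rng, n_sig=5, n_seg=8):
    coeff = pd.DataFrame(
        rng.normal(size=(n_sig, n_seg)),
        index=[f"sig{i}" for i in range(n_sig)],
        columns=[f"seg{i}" for i in range(n_seg)],
    )
    centroids = pd.DataFrame(
        rng.normal(size=(4, n_sig)),
        index=[f"cluster{i + 1}" for i in range(4)],
        columns=coeff.index,
    )
    return CNSignatureModel(coefficients=coeff, centroids=centroids)


class TestScoreSignatures:
    def test_hand_computed_dot_product(self, rng):
        model = CNSignatureModel(
            coefficients=pd.DataFrame(
                [[1.0, -2.0]], index=["s"], columns=["a", "b"]
            ),
            centroids=pd.DataFrame(
                np.zeros((4, 1)),
                index=[f"cluster{i + 1}" for i in range(4)],
                columns=["s"],
            ),
        )
        segvec = pd.Series({"a": 0.5, "b": 0.25})
        assert score_signatures(segvec, model)["s"] == pytest.approx(0.0)

    def test_zero_coefficients_give_zero(self, rng):
        model = _toy_model(rng)
        model = CNSignatureModel(
            coefficients=model.coefficients * 0.0, centroids=model.centroids
        )
        segvec = pd.Series(rng.normal(size=8), index=model.segments)
        assert np.allclose(score_signatures(segvec, model), 0.0)

    def test_linearity(self, rng):
        model = _toy_model(rng)
        x = pd.Series(rng.normal(size=8), index=model.segments)
        y = pd.Series(rng.normal(size=8), index=model.segments)
        lhs = score_signatures(2.0 * x + 3.0 * y, model)
        rhs = 2.0 * score_signatures(x, model) + 3.0 * score_signatures(y, model)
        assert np.allclose(lhs, rhs)

    def test_doubling_signals_doubles_scores(self, rng):
        model = _toy_model(rng)
        x = pd.Series(rng.normal(size=8), index=model.segments)
        assert np.allclose(score_signatures(2 * x, model), 2 * score_signatures(x, model))

    def test_excess_missingness_rejected(self, rng):
        model = _toy_model(rng)
        x = pd.Series(rng.normal(size=8), index=model.segments)
        x.iloc[:3] = np.nan  # 37.5% missing > 20%
        with pytest.raises(CNQualityError):
            score_signatures(x, model)
        assert score_signatures(x, model, max_missing_fraction=0.5) is not None


class TestAssignCluster:
    def test_exact_centroid_recovers_cluster_with_zero_distance(self, rng):
        model = _toy_model(rng)
        scores = model.centroids.loc["cluster3"]
        call = assign_cluster(scores, model)
        assert call.cluster == "cluster3"
        assert call.distances["cluster3"] == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_tie_breaks_low_and_flags(self, rng):
        model = _toy_model(rng)
        mid = (model.centroids.loc["cluster1"] + model.centroids.loc["cluster2"]) / 2
        # force exact equidistance by placing the other centroids far away
        far = model.centroids.copy()
        far.loc["cluster3"] += 100
        far.loc["cluster4"] += 100
        model = CNSignatureModel(coefficients=model.coefficients, centroids=far)
        call = assign_cluster(mid, model)
        assert call.cluster == "cluster1"
        assert call.tie

    def test_matches_brute_force_enumeration(self, rng):
        # oracle: explicit distance comparison over random toy problems
        for _ in range(20):
            model = _toy_model(rng)
            scores = pd.Series(rng.normal(size=5), index=model.signatures)
            call = assign_cluster(scores, model)
            d = {
                k: float(np.sqrt(((scores - model.centroids.loc[k]) ** 2).sum()))
                for k in model.centroids.index
            }
            assert call.cluster == min(sorted(d), key=lambda k: d[k])

    def test_standardization_applied_when_model_provides_it(self, rng):
        base = _toy_model(rng)
        means = pd.Series(1.0, index=base.signatures)
        sds = pd.Series(2.0, index=base.signatures)
        model = CNSignatureModel(
            coefficients=base.coefficients,
            centroids=base.centroids,
            standardize_means=means,
            standardize_sds=sds,
        )
        raw = pd.Series(rng.normal(size=5), index=base.signatures)
        standardized_by_hand = (raw - 1.0) / 2.0
        assert (
            assign_cluster(raw, model).cluster
            == assign_cluster(standardized_by_hand, base).cluster
        )

    def test_missing_scores_rejected(self, rng):
        model = _toy_model(rng)
        scores = pd.Series(np.nan, index=model.signatures)
        with pytest.raises(CNModelError):
            assign_cluster(scores, model)

    def test_centroid_order_irrelevant_without_ties(self, rng):
        model = _toy_model(rng)
        scores = pd.Series(rng.normal(size=5), index=model.signatures)
        shuffled = CNSignatureModel(
            coefficients=model.coefficients,
            centroids=model.centroids.iloc[::-1],
        )
        assert assign_cluster(scores, model).cluster == assign_cluster(scores, shuffled).cluster


def test_pipeline_determinism(small_bundle):
    """Same SEG input + model -> bit-identical scores and clusters."""
    from celtilkit.copynumber import score_cohort

    m = small_bundle.models
    a = score_cohort(small_bundle.seg_profiles, m.annotation,
                     m.segment_definitions, m.cn_model)
    b = score_cohort(small_bundle.seg_profiles, m.annotation,
                     m.segment_definitions, m.cn_model)
    assert a[1].equals(b[1]) and a[2].equals(b[2])


def test_cluster_recovery_improves_as_noise_shrinks():
    from celtilkit.copynumber import score_cohort
    from celtilkit.simulate import CohortConfig, generate_cohort

    accuracies = []
    for noise in (0.6, 0.15, 0.0):
        b = generate_cohort(
            CohortConfig(n_patients=30, seed=4, cn_noise_sd=noise,
                         include_expression=False, include_variants=False)
        )
        m = b.models
        _, _, clusters = score_cohort(
            b.seg_profiles, m.annotation, m.segment_definitions, m.cn_model
        )
        gt = b.ground_truth["cn_cluster"]
        accuracies.append(float((clusters.loc[gt.index] == gt).mean()))
    assert accuracies[-1] == 1.0  # zero noise -> perfect recovery
    assert accuracies[0] <= accuracies[1] <= accuracies[2]
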