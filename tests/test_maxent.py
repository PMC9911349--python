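"""Maximum-entropy site models: closed forms, IPF, scanning, deltas."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncexport import maxent
from lncexport.maxent import (
    DONOR_CONSENSUS,
    MotifModel,
    PWMModel,
    delta_score,
    encode_sites,
    scan_sequence,
    u1_density,
    variant_delta,
)

sites_strategy = st.lists(
    st.text(alphabet="ACGT", min_size=9, max_size=9), min_size=2, max_size=30
)


def random_sites(rng, n, width=9, p=None):
    p = p or [0.25] * 4
    return ["".join(rng.choice(list("ACGT"), size=width, p=p)) for _ in range(n)]


def noisy_consensus(rng, n, rate=0.2):
    out = []
    for _ in range(n):
        out.append(
            "".join(
                b if rng.random() > rate else "ACGT"[rng.integers(4)]
                for b in DONOR_CONSENSUS
            )
        )
    return out


class TestFitting:
    def test_order1_is_product_of_marginals(self, rng):
        sites = random_sites(rng, 200, p=[0.4, 0.1, 0.2, 0.3])
        model = MotifModel.fit(sites, constraint_order=1)
        codes = encode_sites(sites, 9)
        singles = maxent._single_marginals(codes, 9)
        expected = singles[0]
        for j in range(1, 9):
            expected = np.multiply.outer(expected, singles[j])
        assert np.allclose(model.joint, expected)

    def test_normalization_to_1e9(self, rng):
        for order in (1, 2):
            model = MotifModel.fit(noisy_consensus(rng, 100), constraint_order=order)
            assert abs(model.normalization() - 1.0) < 1e-9

    def test_order2_reproduces_pairwise_marginals(self, rng):
        sites = noisy_consensus(rng, 300)
        model = MotifModel.fit(sites, constraint_order=2)
        codes = encode_sites(sites, 9)
        targets = maxent._pair_marginals(codes, 9)
        axes = set(range(9))
        for (i, j), target in targets.items():
            cur = model.joint.sum(axis=tuple(sorted(axes - {i, j})))
            assert np.abs(cur - target).max() < 1e-3

    def test_order1_closed_form_equals_ipf(self, rng):
        """IPF run on the pairwise marginals of an independent distribution
        must converge to the product form (order-1 oracle equivalence)."""
        sites = random_sites(rng, 400, width=5, p=[0.4, 0.1, 0.2, 0.3])
        m1 = MotifModel.fit(sites, constraint_order=1, width=5)
        codes = encode_sites(sites, 5)
        singles = maxent._single_marginals(codes, 5)
        # pairwise targets consistent with independence
        targets = {
            (i, j): np.multiply.outer(singles[i], singles[j])
            for i, j in itertools.combinations(range(5), 2)
        }
        fitted = maxent._ipf(5, targets, tol=1e-9, max_sweeps=2000)
        assert np.abs(fitted - m1.joint).max() < 1e-6

    def test_uniform_training_scores_near_zero(self):
        rng = np.random.default_rng(123)
        sites = random_sites(rng, 10_000)
        model = MotifModel.fit(sites, constraint_order=1)
        probe = random_sites(rng, 200)
        scores = np.array([model.score_site(s) for s in probe])
        assert np.abs(scores).mean() < 0.1

    def test_empty_or_bad_training_rejected(self):
        with pytest.raises(ValueError):
            MotifModel.fit([])
        with pytest.raises(ValueError):
            MotifModel.fit(["ACGTNACGT"])


class TestScoring:
    def test_single_site_training_makes_that_site_the_mode(self):
        model = MotifModel.fit([DONOR_CONSENSUS], constraint_order=1)
        idx = tuple(encode_sites([DONOR_CONSENSUS], 9)[0])
        assert model.joint[idx] == model.joint.max()

    def test_background_equal_to_model_gives_zero_scores(self, rng):
        sites = random_sites(rng, 100, p=[0.4, 0.1, 0.2, 0.3])
        m = MotifModel.fit(sites, constraint_order=1)
        m.background = m.single_targets.copy()
        for s in sites[:10]:
            assert m.score_site(s) == pytest.approx(0.0, abs=1e-9)

    def test_consensus_beats_random_sites(self, rng):
        model = MotifModel.fit(noisy_consensus(rng, 300), pseudocount=0.5)
        consensus_score = model.score_site(DONOR_CONSENSUS)
        random_scores = model.score_codes(rng.integers(0, 4, size=(1_000, 9)))
        assert consensus_score > np.median(random_scores)

    def test_vectorized_scores_match_scalar(self, rng):
        model = MotifModel.fit(noisy_consensus(rng, 100), pseudocount=0.5)
        probe = random_sites(rng, 20)
        vec = model.score_codes(encode_sites(probe, 9))
        for s, v in zip(probe, vec):
            assert model.score_site(s) == pytest.approx(float(v))

    def test_serialization_round_trip(self, tmp_path, rng):
        model = MotifModel.fit(noisy_consensus(rng, 150), pseudocount=0.5)
        model.calibrate_strong_threshold(np.random.default_rng(1))
        model.to_json(tmp_path / "m.json")
        loaded = MotifModel.from_json(tmp_path / "m.json")
        probe = random_sites(rng, 25)
        for s in probe:
            assert loaded.score_site(s) == pytest.approx(model.score_site(s), abs=1e-6)
        assert loaded.strong_threshold == pytest.approx(model.strong_threshold)

    def test_pwm_fallback_agrees_on_ranking(self, rng):
        sites = noisy_consensus(rng, 300)
        pwm = PWMModel.fit(sites)
        assert pwm.score_site(DONOR_CONSENSUS) > pwm.score_site("TTTTTTTTT")


class TestScan:
    def test_sequence_shorter_than_width_is_empty(self, u1_model):
        hits, skipped = scan_sequence(u1_model, "ACGT")
        assert hits == [] and skipped == 0

    def test_ambiguous_windows_skipped_and_tallied(self, u1_model):
        hits, skipped = scan_sequence(u1_model, "ACGTACGTNACGTACGT")
        assert skipped == 9
        assert all(h.score is not None for h in hits)

    def test_planted_consensus_recovered_as_strong(self):
        rng = np.random.default_rng(7)
        model = MotifModel.fit(noisy_consensus(rng, 300), pseudocount=0.5)
        model.calibrate_strong_threshold(np.random.default_rng(1), quantile=0.95)
        background = "".join(rng.choice(list("ACGT"), size=400))
        seq = background[:200] + DONOR_CONSENSUS + background[200:]
        hits, _ = scan_sequence(model, seq)
        strong_at = {h.position for h in hits if h.strong}
        assert 200 in strong_at

    def test_density_arithmetic(self):
        hits = [
            maxent.MotifHit("g", i, 5.0, "exonic", strong=i < 4) for i in range(8)
        ]
        assert u1_density(hits, 2_000, strong_only=True) == pytest.approx(2.0)
        assert u1_density(hits, 2_000, strong_only=False) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            u1_density(hits, 0)

    def test_genic_density_is_length_weighted_combination(self, u1_model, small_sim):
        """Genic hit counts = exonic + intronic hit counts on a gene whose
        donor windows are excluded from both region tallies."""
        from lncexport.io import get_genic_sequence

        m = next(m for m in small_sim["models"] if m.introns)
        genic = get_genic_sequence(m, small_sim["sequences"])
        # exon/intron labels in transcript orientation
        span0 = m.span[0]
        pos_labels = np.empty(m.genic_length, dtype=object)
        pos_labels[:] = "intronic"
        for s, e in m.exons:
            pos_labels[s - span0 : e - span0] = "exonic"
        if m.strand == "-":
            pos_labels = pos_labels[::-1]
        hits, _ = scan_sequence(u1_model, genic, region_mask=list(pos_labels))
        n_ex = sum(1 for h in hits if h.strong and h.region == "exonic")
        n_in = sum(1 for h in hits if h.strong and h.region == "intronic")
        n_all = sum(1 for h in hits if h.strong)
        ex_d = n_ex / (m.exonic_length / 1_000)
        in_d = n_in / (m.intronic_length / 1_000)
        genic_d = u1_density(hits, m.genic_length)
        combined = (ex_d * m.exonic_length + in_d * m.intronic_length) / m.genic_length
        assert n_ex + n_in == n_all
        assert genic_d == pytest.approx(combined)


class TestDelta:
    def test_identical_contexts_neutral(self, u1_model):
        d, call = delta_score(u1_model, DONOR_CONSENSUS, DONOR_CONSENSUS)
        assert d == 0.0 and call == "neutral"

    def test_every_core_disruption_weakens_consensus(self, rng):
        model = MotifModel.fit(noisy_consensus(rng, 500), pseudocount=0.5)
        # brute force over all single changes of the GT core (positions 3, 4)
        for pos in (3, 4):
            for alt in "ACGT":
                if alt == DONOR_CONSENSUS[pos]:
                    continue
                mutated = DONOR_CONSENSUS[:pos] + alt + DONOR_CONSENSUS[pos + 1 :]
                d, call = delta_score(model, DONOR_CONSENSUS, mutated)
                assert d < 0 and call == "weaken"

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, data):
        rng = np.random.default_rng(0)
        model = MotifModel.fit(noisy_consensus(rng, 100), pseudocount=0.5)
        ref = data.draw(st.text(alphabet="ACGT", min_size=9, max_size=9))
        pos = data.draw(st.integers(0, 8))
        alt_base = data.draw(st.sampled_from("ACGT"))
        alt = ref[:pos] + alt_base + ref[pos + 1 :]
        d1, _ = delta_score(model, ref, alt)
        d2, _ = delta_score(model, alt, ref)
        assert d1 == pytest.approx(-d2)

    def test_variant_out_of_any_window(self, u1_model):
        d, call = variant_delta(u1_model, "NNNNANNNN", 4, "A", "G")
        assert d is None and call == "out_of_window"

    def test_variant_delta_uses_best_window(self, rng):
        model = MotifModel.fit(noisy_consensus(rng, 500), pseudocount=0.5)
        seq = "TTTTTTTT" + DONOR_CONSENSUS + "TTTTTTTT"
        # disrupt the G of the GT core (position 3 of the consensus)
        d, call = variant_delta(model, seq, 8 + 3, DONOR_CONSENSUS[3], "C")
        assert d < 0 and call == "weaken"
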