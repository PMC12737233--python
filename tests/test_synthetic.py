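"""Synthetic cohort generator: determinism, calibration, and geometry."""

import numpy as np
import pandas as pd
import pytest

from gaitpheno.config import SignalConfig
from gaitpheno.synthetic import (
    PhenotypeArchetype,
    assign_fall_labels,
    default_archetypes,
    generate_cohort,
    generate_subject_strides,
)


class TestArchetypes:
    def test_phase_fractions_sum_to_one(self):
        for sep in (0.0, 1.0, 2.5):
            for a in default_archetypes(sep):
                assert abs(sum(a.phase_fractions) - 1.0) < 1e-9

    def test_zero_separation_collapses_archetypes(self):
        arch = default_archetypes(0.0)
        for f in ("cadence_mean", "step_speed_mean", "stride_length_mean"):
            vals = [getattr(a, f) for a in arch]
            assert np.ptp(vals) < 1e-9

    def test_invalid_archetype_rejected(self):
        base = default_archetypes()[0]
        with pytest.raises(ValueError, match="sum to 1"):
            PhenotypeArchetype(
                name="bad", cadence_mean=50, step_speed_mean=1, stride_length_mean=1,
                clearance_mean=0.1, phase_fractions=(0.3, 0.3, 0.3, 0.3),
                clinical_means=base.clinical_means,
                within_phenotype_sd=base.within_phenotype_sd,
                fall_driver="tug_s", driver_coefficient=1.0, base_prevalence=0.5,
            )


class TestGenerateCohort:
    def test_near_equal_split_146(self, signal_config):
        cohort = generate_cohort(
            default_archetypes(), 146, signal_config, seed=7, n_strides_range=(5, 6)
        )
        sizes = cohort.true_phenotype.value_counts().sort_values(ascending=False)
        assert sorted(sizes.tolist(), reverse=True) == [37, 37, 36, 36]

    def test_determinism(self, signal_config):
        a = generate_cohort(default_archetypes(), 16, signal_config, seed=7,
                            n_strides_range=(5, 6))
        b = generate_cohort(default_archetypes(), 16, signal_config, seed=7,
                            n_strides_range=(5, 6))
        pd.testing.assert_frame_equal(a.features, b.features)
        assert a.features.to_csv() == b.features.to_csv()
        for sid in a.subject_ids:
            for sa, sb in zip(a.strides[sid], b.strides[sid]):
                assert np.array_equal(sa.channels(), sb.channels())

    def test_empirical_cadence_matches_archetype(self, signal_config):
        """Monte-Carlo check: per-phenotype mean derived cadence within 2%
        of the archetype parameter."""
        arch = default_archetypes()
        cohort = generate_cohort(arch, 800, signal_config, seed=1,
                                 n_strides_range=(8, 12))
        df = cohort.features.join(cohort.true_phenotype)
        for a in arch:
            emp = df[df.phenotype == a.name]["cadence"].mean()
            assert abs(emp - a.cadence_mean) / a.cadence_mean < 0.02

    def test_errors(self, signal_config):
        with pytest.raises(ValueError, match="positive"):
            generate_cohort(default_archetypes(), 0, signal_config, seed=1)
        with pytest.raises(ValueError, match="empty"):
            generate_cohort([], 10, signal_config, seed=1)

    def test_missingness_injection(self, signal_config):
        cohort = generate_cohort(
            default_archetypes(), 200, signal_config, seed=3,
            n_strides_range=(5, 6), missing_rate=0.05,
        )
        frac = cohort.features[["gds", "sppb", "tug_s"]].isna().mean().mean()
        assert 0.01 < frac < 0.12
        # gait parameters derived from strides are never masked
        assert cohort.features["cadence"].notna().all()


class TestSubjectStrides:
    def test_zero_noise_zero_jitter_identical(self, signal_config, rng):
        arch = default_archetypes()[0]
        strides = generate_subject_strides(
            arch, {}, 5, signal_config, rng,
            noise_sd=(0, 0, 0), timing_jitter_rel=0.0, scalar_jitter=(0, 0),
        )
        ref = strides[0].channels()
        for s in strides[1:]:
            assert np.array_equal(s.channels(), ref)

    def test_duration_follows_cadence(self, signal_config, rng):
        """Stride duration is 60/cadence: 53.7 vs 46.5 strides/min give mean
        durations near 1.117 s and 1.290 s."""
        for cadence, expected in ((53.7, 60 / 53.7), (46.5, 60 / 46.5)):
            arch = default_archetypes()[0]
            eff = {"cadence": cadence - arch.cadence_mean}
            strides = generate_subject_strides(
                arch, eff, 40, signal_config, rng, timing_jitter_rel=0.0
            )
            durs = [s.n_samples / signal_config.sampling_rate_hz for s in strides]
            assert abs(np.mean(durs) - expected) < 0.01

    def test_push_fraction_moves_pushoff_peak(self, signal_config, rng):
        arch = default_archetypes()[0]
        base = generate_subject_strides(
            arch, {}, 1, signal_config, rng,
            noise_sd=(0, 0, 0), timing_jitter_rel=0.0, scalar_jitter=(0, 0),
        )[0]
        bump = 0.5 * arch.phase_fractions[2]  # +50% push, taken from swing
        shifted = generate_subject_strides(
            arch, {"push": bump, "swing": -bump}, 1, signal_config, rng,
            noise_sd=(0, 0, 0), timing_jitter_rel=0.0, scalar_jitter=(0, 0),
        )[0]
        assert (
            np.argmax(shifted.acc_y) / shifted.n_samples
            > np.argmax(base.acc_y) / base.n_samples
        )

    def test_nonpositive_cadence_rejected(self, signal_config, rng):
        arch = default_archetypes()[0]
        with pytest.raises(ValueError, match="cadence"):
            generate_subject_strides(
                arch, {"cadence": -arch.cadence_mean}, 3, signal_config, rng
            )


class TestFallLabels:
    def test_zero_coefficient_reduces_to_constant(self, signal_config):
        from dataclasses import replace

        arch = [replace(a, driver_coefficient=0.0) for a in default_archetypes()]
        cohort = generate_cohort(arch, 1200, signal_config, seed=9,
                                 n_strides_range=(5, 6))
        df = cohort.features.join(cohort.true_phenotype)
        for a in arch:
            grp = df[df.phenotype == a.name]
            se = np.sqrt(a.base_prevalence * (1 - a.base_prevalence) / len(grp))
            assert abs(grp["fell"].mean() - a.base_prevalence) < 4 * se

    def test_cautious_fallers_walk_slower(self, signal_config):
        """Negative planted slope on 4 m gait speed: fallers slower on average."""
        cohort = generate_cohort(default_archetypes(), 1000, signal_config,
                                 seed=2, n_strides_range=(5, 6))
        df = cohort.features.join(cohort.true_phenotype)
        grp = df[df.phenotype == "cautious"]
        assert (
            grp[grp.fell == 1]["gait_speed_4m"].mean()
            < grp[grp.fell == 0]["gait_speed_4m"].mean()
        )

    def test_unknown_driver_rejected(self, small_cohort, rng):
        from dataclasses import replace

        bad = [replace(a, fall_driver="no_such_feature") for a in default_archetypes()]
        with pytest.raises(ValueError, match="unknown driver"):
            assign_fall_labels(small_cohort, bad, rng)


def test_zero_separation_gives_chance_clustering(signal_config):
    """At separation 0 the archetypes coincide, so waveform clustering can
    only recover the planted labels at chance level."""
    from sklearn.metrics import adjusted_rand_score

    from gaitpheno.clustering import kmedoids
    from gaitpheno.dissimilarity import pairwise_dissimilarity, reduce_channels
    from gaitpheno.config import ReducerConfig
    from gaitpheno.preprocess import representative_curves

    cohort = generate_cohort(default_archetypes(0.0), 60, signal_config, seed=4,
                             n_strides_range=(6, 10))
    reps = [
        representative_curves(cohort.strides[sid], signal_config)
        for sid in cohort.subject_ids
    ]
    series, _ = reduce_channels(reps, ReducerConfig())
    D = pairwise_dissimilarity(series, cohort.subject_ids)
    labels = kmedoids(D.D, 4, seed=0)
    ari = adjusted_rand_score(cohort.true_phenotype.to_numpy(), labels)
    assert abs(ari) < 0.2
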