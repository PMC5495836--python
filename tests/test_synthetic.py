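"""Generator properties: geometry, coupling convergence, optics, cohort."""
import numpy as np
import pytest
from scipy.signal import periodogram

from oiconnect.datatypes import GroundTruth, OpticsConfig
from oiconnect.seed_fc import extract_seed_timecourses
from oiconnect.synthetic import (
    CohortDesign,
    default_coupling,
    effective_coupling,
    forward_optics,
    make_cortex_mask,
    make_seed_atlas,
    simulate_chromophores,
    simulate_cohort,
    simulate_histology,
    simulate_physiology,
)


class TestCortexMask:
    def test_bilateral_symmetry_and_connectivity(self):
        m = make_cortex_mask(64, 64, 4)
        assert np.array_equal(m.mask, m.mask[:, ::-1])
        from scipy import ndimage

        _, n = ndimage.label(m.mask)
        assert n == 1  # simply connected ellipse

    def test_deterministic(self):
        a = make_cortex_mask(64, 64, 4)
        b = make_cortex_mask(64, 64, 4)
        assert np.array_equal(a.mask, b.mask)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            make_cortex_mask(8, 8, 4)


class TestSeedAtlas:
    def test_default_layout(self):
        atlas = make_seed_atlas(make_cortex_mask(128, 128, 4))
        assert atlas.n_seeds == 8
        assert all(len(px) == 17 for px in atlas.seeds.values())
        assert len(atlas.homotopic_pairs) == 4

    def test_custom_four_seed_spec(self, small_mask):
        spec = {"M_L": (25, 20), "M_R": (25, 43), "R_L": (45, 25), "X": (40, 32)}
        atlas = make_seed_atlas(small_mask, spec)
        assert atlas.n_seeds == 4
        # only M has both hemispheres
        assert atlas.homotopic_pairs == [("M_L", "M_R")]

    def test_border_center_insufficient_neighbors(self, small_mask):
        rows, cols = np.nonzero(small_mask.mask)
        # the leftmost in-mask pixel is on the mask border: half its
        # neighbourhood lies outside the cortex
        i = np.argmin(cols)
        with pytest.raises(ValueError, match="in-mask pixels"):
            make_seed_atlas(
                small_mask, {"edge": (int(rows[i]), int(cols[i]))}, max_radius=2.5
            )
        # an interior centre fits 17 pixels inside the same radius
        make_seed_atlas(small_mask, {"mid_L": (31, 31)}, max_radius=2.5)

    def test_center_outside_mask_raises(self, small_mask):
        with pytest.raises(ValueError, match="outside"):
            make_seed_atlas(small_mask, {"out": (0, 0)})

    def test_overlapping_seeds_raise(self, small_mask):
        with pytest.raises(ValueError, match="overlap"):
            make_seed_atlas(small_mask, {"a": (30, 30), "b": (30, 31)})


def _mean_empirical_r(atlas, truth, n_rep, n_frames=2100, **kw):
    acc = np.zeros((atlas.n_seeds, atlas.n_seeds))
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        movie = simulate_chromophores(
            atlas, truth, n_frames, 5.0, rng=rng, packed=True, **kw
        )
        tc = extract_seed_timecourses(movie, atlas, "HbO2")
        acc += np.corrcoef(tc.data.T)
    return acc / n_rep


class TestChromophoreCoupling:
    def test_identity_coupling_null_correlations(self, study_atlas):
        truth = GroundTruth(
            coupling=np.eye(8),
            seed_names=study_atlas.seed_names,
            group="control",
            rng_seed=0,
        )
        r = _mean_empirical_r(study_atlas, truth, n_rep=20)
        off = r[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_homotopic_coupling_recovered(self, study_atlas):
        coupling = default_coupling(study_atlas.seed_names, homotopic=0.8)
        truth = GroundTruth(
            coupling=coupling,
            seed_names=study_atlas.seed_names,
            group="control",
            rng_seed=0,
        )
        r = _mean_empirical_r(study_atlas, truth, n_rep=20)
        names = study_atlas.seed_names
        for left, right in study_atlas.homotopic_pairs:
            rij = r[names.index(left), names.index(right)]
            assert abs(rij - 0.8) < 0.15

    def test_full_lesion_kills_homotopic_coupling(self, study_atlas):
        coupling = default_coupling(study_atlas.seed_names)
        truth = GroundTruth(
            coupling=coupling,
            seed_names=study_atlas.seed_names,
            group="injured",
            lesion_fraction=1.0,
            kappa=1.0,
            rng_seed=0,
        )
        r = _mean_empirical_r(study_atlas, truth, n_rep=10)
        names = study_atlas.seed_names
        for left, right in study_atlas.homotopic_pairs:
            assert abs(r[names.index(left), names.index(right)]) < 0.2

    def test_coupling_convergence_mean_error(self, study_atlas):
        """Replicate-averaged seed correlations converge to the coupling
        matrix (mean absolute error < 0.05 over 50 replicates)."""
        coupling = default_coupling(study_atlas.seed_names)
        truth = GroundTruth(
            coupling=coupling,
            seed_names=study_atlas.seed_names,
            group="control",
            rng_seed=123,
        )
        r = _mean_empirical_r(study_atlas, truth, n_rep=50)
        err = np.abs(r - coupling)[~np.eye(8, dtype=bool)]
        assert err.mean() < 0.05

    def test_band_limited_power(self, small_atlas, control_truth):
        movie = simulate_chromophores(
            small_atlas, control_truth, 2100, 5.0, packed=True
        )
        tc = extract_seed_timecourses(movie, small_atlas, "HbO2")
        f, p = periodogram(tc.data[:, 0], fs=5.0)
        inband = (f >= 0.009 - 1e-9) & (f <= 0.08 + 1e-9)
        assert p[~inband].sum() < 0.01 * p.sum()

    def test_reproducible(self, small_atlas, control_truth):
        a = simulate_chromophores(small_atlas, control_truth, 300, 5.0)
        b = simulate_chromophores(small_atlas, control_truth, 300, 5.0)
        assert np.array_equal(a.data["HbO2"], b.data["HbO2"])
        assert np.array_equal(a.data["HbR"], b.data["HbR"])

    def test_packed_matches_frames(self, small_atlas, control_truth):
        packed = simulate_chromophores(
            small_atlas, control_truth, 300, 5.0, packed=True
        )
        frames = simulate_chromophores(small_atlas, control_truth, 300, 5.0)
        rows, cols = packed.pixels
        assert np.array_equal(packed.data["HbO2"], frames.data["HbO2"][:, rows, cols])

    def test_non_psd_effective_coupling_raises(self, small_atlas, control_truth):
        truth = GroundTruth(
            coupling=control_truth.coupling,
            seed_names=small_atlas.seed_names,
            group="control",
            rng_seed=0,
        )
        c = truth.coupling.copy()
        c[0, 1] = c[1, 0] = 0.99
        c[0, 2] = c[2, 0] = 0.99
        c[1, 2] = c[2, 1] = -0.99  # wildly inconsistent triangle
        truth.coupling = c  # bypasses construction-time validation
        with pytest.raises(ValueError, match="positive semidefinite"):
            effective_coupling(truth)


class TestPhysiology:
    def test_reproducible_and_sized(self):
        a = simulate_physiology(2100, 5.0, 7)
        b = simulate_physiology(2100, 5.0, 7)
        assert a.n_samples == 2100
        assert np.array_equal(a.resp_signal, b.resp_signal)

    def test_respiration_spectral_peak(self):
        tr = simulate_physiology(2100, 5.0, 3, resp_hz=1.0)
        f, p = periodogram(tr.resp_signal - tr.resp_signal.mean(), fs=5.0)
        assert abs(f[np.argmax(p)] - 1.0) < 0.15


class TestForwardOptics:
    def test_zero_concentration_gives_reference_intensity(self, small_atlas):
        truth = GroundTruth(
            coupling=np.eye(8), seed_names=small_atlas.seed_names,
            group="control", rng_seed=0,
        )
        movie = simulate_chromophores(small_atlas, truth, 200, 5.0)
        for k in movie.data:
            movie.data[k][:] = 0.0
        cfg = OpticsConfig(noise_sd=0.0)
        stack = forward_optics(movie, cfg)
        assert np.allclose(stack.intensities, cfg.i0)

    def test_optical_density_linear_in_concentration(self, small_atlas, control_truth):
        cfg = OpticsConfig(noise_sd=0.0)
        movie = simulate_chromophores(
            small_atlas, control_truth, 200, 5.0, dtype=np.float64
        )
        stack1 = forward_optics(movie, cfg)
        for k in movie.data:
            movie.data[k] *= 2.0
        stack2 = forward_optics(movie, cfg)
        dod1 = -np.log10(stack1.intensities / cfg.i0)
        dod2 = -np.log10(stack2.intensities / cfg.i0)
        assert np.allclose(dod2, 2 * dod1, atol=1e-10)


class TestCohort:
    def test_counts_and_labels(self):
        design = CohortDesign(shape=(64, 64), n_frames=150, include_optics=False,
                              include_physio=False)
        cohort = simulate_cohort(8, 5, design, rng_seed=42)
        assert len(cohort) == 13
        assert cohort.labels.count("control") == 8
        assert all(t.lesion_fraction == 0 for t in cohort.truths[:8])
        assert all(0.6 <= t.lesion_fraction <= 1.0 for t in cohort.truths[8:])

    def test_bit_reproducible(self):
        design = CohortDesign(shape=(64, 64), n_frames=150, include_optics=False)
        a = simulate_cohort(2, 2, design, rng_seed=5).subject(1)
        b = simulate_cohort(2, 2, design, rng_seed=5).subject(1)
        assert np.array_equal(a.chromo.data["HbO2"], b.chromo.data["HbO2"])
        assert np.array_equal(a.physio.ecg, b.physio.ecg)

    def test_injury_lowers_homotopic_correlation(self):
        design = CohortDesign(
            shape=(64, 64), n_frames=1200, include_optics=False,
            include_physio=False, packed=True,
        )
        cohort = simulate_cohort(4, 4, design, rng_seed=11)
        means = {"control": [], "injured": []}
        for i in range(len(cohort)):
            s = cohort.subject(i)
            tc = extract_seed_timecourses(s.chromo, cohort.atlas, "HbO2")
            r = np.corrcoef(tc.data.T)
            names = cohort.atlas.seed_names
            vals = [
                r[names.index(a), names.index(b)]
                for a, b in cohort.atlas.homotopic_pairs
            ]
            means[s.truth.group].append(np.mean(vals))
        assert np.mean(means["injured"]) < np.mean(means["control"])


class TestHistologyPhantom:
    def test_zero_lesion_has_no_ventricle(self):
        stack = simulate_histology(0.0, n_slices=6, px_per_mm=40)
        # nothing brighter than tissue (110) beyond noise
        assert stack.slices.max() < 140

    def test_reproducible(self):
        a = simulate_histology(0.2, n_slices=4, px_per_mm=40, rng_seed=9)
        b = simulate_histology(0.2, n_slices=4, px_per_mm=40, rng_seed=9)
        assert np.array_equal(a.slices, b.slices)

    def test_lesion_fraction_bounds(self):
        with pytest.raises(ValueError):
            simulate_histology(1.5, n_slices=4, px_per_mm=40)
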