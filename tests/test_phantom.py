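"""Phantom/cohort generator: geometry oracles, noise models, determinism."""

import numpy as np
import pytest

from glymap import phantom as ph
from glymap import quantify, t2relax


class TestGeometry:
    def test_fraction_simplex_and_mask_algebra(self, small_phantom):
        p = small_phantom
        f = p.fractions
        total = f["f_mw"] + f["f_ie"] + f["f_csf"]
        assert np.allclose(total[p.brain_mask], 1.0)
        assert np.all(f["f_csf"][p.brain_mask] >= 0)
        assert np.all(f["f_mw"][p.brain_mask] >= 0)
        # mask containment: wmh and pvs in WM, admask/reference in GM, all in brain
        assert np.all(p.masks["wmh"] <= p.masks["wm"])
        assert np.all(p.masks["pvs_truth"] <= p.masks["wm"])
        assert np.all(p.masks["admask"] <= p.masks["gm"])
        assert np.all(p.masks["cerebellum_ref"] <= p.masks["gm"])
        for m in p.masks.values():
            assert np.all(m <= p.brain_mask)
        # tensors PSD everywhere
        ev = np.linalg.eigvalsh(p.tissue_tensor[p.brain_mask])
        assert ev.min() >= -1e-15
        assert p.fw_truth.min() >= 0 and p.fw_truth.max() <= 1

    def test_tubule_volume_matches_voxel_scan_oracle(self):
        # independent brute-force scan of the analytic cylinder
        shape = (32, 32, 32)
        tub = ph.PvsTubule(axis=0, offset=(0.0, 7.0), radius_vox=1.0, length_vox=10)
        c = [(s - 1) / 2.0 for s in shape]
        count = 0
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    in_len = abs(x - c[0]) <= tub.length_vox / 2.0
                    r2 = (y - (c[1] + tub.offset[0])) ** 2 + (z - (c[2] + tub.offset[1])) ** 2
                    if in_len and r2 <= tub.radius_vox**2:
                        count += 1
        spec = ph.PhantomSpec(tubules=(tub,))
        p = ph.make_phantom(shape, spec, seed=0)
        assert int(p.masks["pvs_truth"].sum()) == count

    def test_same_seed_is_bit_identical(self):
        spec = ph.PhantomSpec(fraction_jitter_sd=0.01)
        a = ph.make_phantom((32, 32, 32), spec, seed=7)
        b = ph.make_phantom((32, 32, 32), spec, seed=7)
        assert np.array_equal(a.fractions["f_csf"], b.fractions["f_csf"])
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("shape", [(8, 32, 32), (15, 15, 15)])
    def test_degenerate_shape_rejected(self, shape):
        with pytest.raises(ValueError, match="degenerate"):
            ph.make_phantom(shape)

    def test_oversized_tubule_rejected(self):
        spec = ph.PhantomSpec(tubules=(ph.PvsTubule(radius_vox=30.0),))
        with pytest.raises(ValueError, match="radius"):
            ph.make_phantom((32, 32, 32), spec)


class TestAcquisitionSpec:
    def test_study_protocol_defaults(self, dwi_acq):
        assert tuple(dwi_acq.t2prep_times_ms) == (0.0, 7.5, 17.5, 67.5, 147.5, 307.5)
        nz = dwi_acq.bvals_arr[dwi_acq.bvals_arr > 0]
        assert set(nz) == {1500.0, 3000.0}
        assert nz.size == 98
        assert dwi_acq.n_shells() == 2

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"t2prep_times_ms": (7.5, 17.5, 67.5, 147.5)}, "start at 0"),
            ({"t2prep_times_ms": (0.0, 7.5, 7.5)}, "increasing"),
            ({"bvals": (0.0, 1500.0), "bvecs": ((0, 0, 0), (1.0, 1.0, 0.0))}, "unit norm"),
            ({"bvals": (0.0,), "bvecs": ()}, "equal"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            ph.AcquisitionSpec(**kwargs)


class TestMultiEcho:
    def test_noise_free_equals_forward_model(self, small_phantom, fast_t2_times):
        series = ph.simulate_multiecho(small_phantom, snr=np.inf)
        # t = 0: all exponentials are 1, so signal = m0 everywhere
        assert np.allclose(series.data[..., 0], small_phantom.m0)
        # spot-check a WM voxel against the scalar forward model
        idx = tuple(np.argwhere(small_phantom.masks["wm"])[0])
        f = [small_phantom.fractions[k][idx] for k in ("f_mw", "f_ie", "f_csf")]
        expected = t2relax.predict_signal(f, small_phantom.t2_ms, small_phantom.m0[idx],
                                          fast_t2_times)
        assert np.allclose(series.data[idx], expected)

    def test_known_signal_value(self, fast_t2_times):
        # f = (0.1, 0.85, 0.05), T2 = (20, 80, 2000) ms at t = 307.5 ms
        sig = t2relax.predict_signal((0.1, 0.85, 0.05), (20, 80, 2000), 1.0, [307.5])
        assert sig[0] == pytest.approx(0.0611, abs=5e-5)

    def test_rician_floor_at_zero_signal(self):
        rng = np.random.default_rng(0)
        sigma = 0.2
        samples = ph.add_rician_noise(np.zeros(10_000), sigma, rng)
        expected = sigma * np.sqrt(np.pi / 2.0)
        assert samples.mean() == pytest.approx(expected, rel=0.02)

    def test_noise_determinism(self, small_phantom):
        a = ph.simulate_multiecho(small_phantom, snr=50, seed=3)
        b = ph.simulate_multiecho(small_phantom, snr=50, seed=3)
        assert np.array_equal(a.data, b.data)


class TestDwi:
    def test_pure_free_water_attenuation(self, dwi_acq):
        spec = ph.PhantomSpec()
        p = ph.make_phantom((32, 32, 32), spec)
        dwi = ph.simulate_dwi(p, dwi_acq, snr=np.inf)
        csf_idx = tuple(np.argwhere(p.labels == 3)[0])
        b = dwi.bvals
        s = dwi.data[csf_idx]
        # fw = 1 voxel: S/S0 = e^{-b d_iso}; at b = 1500 that is 0.0111
        assert s[b == 0][0] == pytest.approx(1.0)
        assert np.allclose(s[b == 1500] / s[b == 0][0], np.exp(-4.5), atol=1e-9)

    def test_b0_equals_s0_everywhere(self, small_phantom, dwi_acq):
        dwi = ph.simulate_dwi(small_phantom, dwi_acq, snr=np.inf)
        for j in np.flatnonzero(dwi.bvals == 0):
            assert np.allclose(dwi.data[..., j], small_phantom.m0)

    def test_two_term_mixture_value(self):
        from glymap.fwdti import bitensor_signal

        s = bitensor_signal(np.eye(3) * 0.7e-3, 0.3, 1.0, [1500.0], [(1.0, 0.0, 0.0)])
        assert s[0] == pytest.approx(0.2483, abs=5e-5)

    def test_single_shell_refused(self, small_phantom):
        dirs = ph.fibonacci_directions(10)
        acq = ph.AcquisitionSpec(bvals=(0.0,) + (1500.0,) * 10,
                                 bvecs=((0.0, 0.0, 0.0),) + tuple(map(tuple, dirs)))
        with pytest.raises(ph.IdentifiabilityError):
            ph.simulate_dwi(small_phantom, acq)


class TestStructuralAndPet:
    def test_noise_free_structural_is_piecewise_constant(self, small_phantom):
        contrast = ph.ContrastSpec(noise_sd=0.0)
        t1w, t2w = ph.simulate_structural(small_phantom, contrast)
        wm_plain = small_phantom.masks["wm"] & ~small_phantom.masks["pvs_truth"] \
            & ~small_phantom.masks["wmh"]
        assert np.unique(t1w[wm_plain]).size == 1
        assert np.unique(t2w[small_phantom.masks["pvs_truth"]]).size == 1

    def test_epc_darker_inside_pvs(self, small_phantom):
        from glymap.pvs_morph import compute_epc

        t1w, t2w = ph.simulate_structural(small_phantom, seed=5)
        epc = compute_epc(t1w, t2w, small_phantom.brain_mask)
        pvs = small_phantom.masks["pvs_truth"]
        wm_rest = small_phantom.masks["wm"] & ~pvs
        assert epc.data[pvs].mean() < epc.data[wm_rest].mean()

    def test_structural_determinism(self, small_phantom):
        a = ph.simulate_structural(small_phantom, seed=11)
        b = ph.simulate_structural(small_phantom, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_nonpositive_intensity_rejected(self, small_phantom):
        bad = ph.ContrastSpec(t1w={"gm": 0.7, "wm": -1.0, "csf": 0.2, "pvs": 0.5, "wmh": 0.8})
        with pytest.raises(ValueError):
            ph.simulate_structural(small_phantom, bad)

    @pytest.mark.parametrize("suvr", [1.0, 1.17, 2.07])
    def test_noise_free_pet_suvr_exact(self, small_phantom, suvr):
        pet = ph.simulate_pet(small_phantom, suvr, noise_sd=0.0)
        got = quantify.compute_suvr(pet, small_phantom.masks["admask"],
                                    small_phantom.masks["cerebellum_ref"])
        assert got == pytest.approx(suvr, abs=1e-12)

    def test_noisy_pet_suvr_unbiased(self, small_phantom):
        suvrs = [
            quantify.compute_suvr(
                ph.simulate_pet(small_phantom, 1.5, noise_sd=0.01, seed=k),
                small_phantom.masks["admask"], small_phantom.masks["cerebellum_ref"])
            for k in range(100)
        ]
        se = np.std(suvrs, ddof=1) / 10.0
        assert abs(np.mean(suvrs) - 1.5) <= 3 * se + 1e-6


class TestCohort:
    def test_default_cohort_matches_study_design(self):
        spec = ph.CohortSpec(seed=2)
        cohort = ph.make_cohort(spec)
        assert len(cohort) == 29
        dx = [rec.dx for rec, _ in cohort]
        assert dx.count("NL") == 16 and dx.count("MCIAD") == 13
        for rec, subj in cohort:
            f = subj.fractions
            total = f["f_mw"] + f["f_ie"] + f["f_csf"]
            assert np.allclose(total[subj.brain_mask], 1.0)
            # rescaled truths survive the round trip through TWC (WMH excluded)
            wm_eff = subj.masks["wm"] & ~subj.masks["wmh"]
            assert f["f_csf"][wm_eff].mean() * 0.70 * 100 == pytest.approx(rec.wm_pcsf, abs=1e-9)

    def test_cohort_determinism(self):
        a = ph.make_cohort(ph.CohortSpec(seed=5))
        b = ph.make_cohort(ph.CohortSpec(seed=5))
        assert [r.id for r, _ in a] == [r.id for r, _ in b]
        assert all(ra == rb for (ra, _), (rb, _) in zip(a, b))

    def test_large_cohort_group_means_recovered(self):
        spec = ph.CohortSpec(n_nl=200, n_mciad=200, seed=9)
        recs = [rec for rec, _ in ph.iter_cohort(spec)]
        for dx in ("NL", "MCIAD"):
            vals = np.array([r.wm_pcsf for r in recs if r.dx == dx])
            target = spec.group_means[dx]["wm_pcsf"]
            se = spec.group_sds[dx]["wm_pcsf"] / np.sqrt(len(vals))
            assert abs(vals.mean() - target) <= 3 * se

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ph.CohortSpec(n_nl=1)
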