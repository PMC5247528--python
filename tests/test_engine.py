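"""Difference-map engine: projections, fixed points, modes, gauge."""

import numpy as np
import pytest

from ptychokit import (
    DMEngine,
    EngineParams,
    FrameSet,
    Geometry,
    ScanSpec,
    build_pods,
    fix_ambiguities,
    fourier_update,
    model_intensity,
    object_update,
    orthogonalize_modes,
    probe_update,
)
from conftest import network_at_truth, small_scan


def centred_dft(a):
    """Independent unitary centred DFT (explicit phases, O(N^4))."""
    R, C = a.shape
    out = np.zeros((R, C), dtype=complex)
    for k in range(R):
        for l in range(C):
            s = 0j
            for r in range(R):
                for c in range(C):
                    s += a[r, c] * np.exp(
                        -2j * np.pi * ((k - R // 2) * (r - R // 2) / R
                                       + (l - C // 2) * (c - C // 2) / C)
                    )
            out[k, l] = s / np.sqrt(R * C)
    return out


def centred_idft(a):
    return np.conj(centred_dft(np.conj(a)))


class TestFourierUpdate:
    def test_fixed_point_on_consistent_data(self):
        _, frames, truth = small_scan(grid=(3, 3), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        before = net.containers["exit"].storages["ex"].data.copy()
        for j in net.frame_indices:
            fourier_update(net.pods_of_frame(j), eps=1e-15)
        after = net.containers["exit"].storages["ex"].data
        scale = np.max(np.abs(before))
        assert np.max(np.abs(after - before)) / scale < 1e-10

    def test_fully_masked_frame_snaps_exit_to_model(self, rng):
        _, frames, truth = small_scan(grid=(2, 2), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        net.containers["mask"].storages["m0"].data[...] = 0.0
        pod = net.pods_of_frame(0)[0]
        pod.exit = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        fourier_update(net.pods_of_frame(0), eps=0.0)
        np.testing.assert_allclose(pod.exit, pod.probe * pod.object, atol=1e-10)

    def test_matches_independent_transcription(self, rng):
        """Single 2x2 pod against a step-by-step transcription of the
        feedback/correction/update algebra with the DFT oracle."""
        geom = Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=(2, 2))
        p = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        o = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        psi = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        I = rng.uniform(0.5, 2.0, (2, 2))
        M = np.array([[1.0, 0.0], [1.0, 1.0]])

        spec = ScanSpec(positions=np.zeros((1, 2)), geometry=geom)
        frames = FrameSet(frames=I[None], masks=M[None], geometry=geom)
        net = build_pods(spec, frames)
        pod = net.pods[0]
        pod.probe, pod.object, pod.exit = p, o, psi
        err = fourier_update(net.pods, eps=0.0)

        phi = 2.0 * p * o - psi
        Psi = centred_dft(phi)
        total = np.abs(Psi) ** 2
        Y = 1.0 - M + M * np.sqrt(I / total)
        phi_new = centred_idft(Psi * Y)
        psi_new = psi + phi_new - p * o
        assert np.max(np.abs(pod.exit - psi_new)) < 1e-12
        model_total = np.abs(centred_dft(p * o)) ** 2
        expected_err = np.sum(M * (model_total - I) ** 2) / np.sum(M * I**2)
        assert abs(err - expected_err) < 1e-12

    def test_rejects_empty_and_negative_intensity(self, rng):
        with pytest.raises(ValueError):
            fourier_update([])
        _, frames, truth = small_scan(grid=(2, 2), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        net.containers["diff"].storages["d0"].data[0, 3, 3] = -1.0
        with pytest.raises(ValueError):
            fourier_update(net.pods_of_frame(0))


class TestOverlapUpdates:
    def test_object_recovered_exactly_from_consistent_exits(self):
        _, frames, truth = small_scan(grid=(3, 3), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        storage = net.containers["object"].storages["o0"]
        expected = storage.data.copy()
        storage.data[...] = 123.0 + 4j  # garbage; update must restore
        object_update(net, eps=0.0)
        # covered pixels: weighted average of identical values -> exact
        cov = net.containers["object"].clone("cov").fill(0.0)
        for pod in net.pods:
            cov.window(pod.views["object"])[...] += np.abs(pod.probe) ** 2
        covered = cov.storages["o0"].data.real > 0
        assert np.max(np.abs((storage.data - expected)[covered])) < 1e-9

    def test_unit_probe_gives_plain_average_of_exits(self, rng):
        geom = Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=(2, 4))
        rp = geom.rpsize
        # two scan points one object-pixel apart in x
        positions = np.array([[0.0, 0.0], [0.0, -rp[1]]])
        frames = FrameSet(frames=np.zeros((2, 2, 4)), masks=np.ones((1, 2, 4)),
                          geometry=geom)
        net = build_pods(ScanSpec(positions=positions, geometry=geom), frames)
        net.containers["probe"].storages["p0"].data[...] = 1.0
        exits = rng.standard_normal((2, 2, 4)) + 1j * rng.standard_normal((2, 2, 4))
        for pod, e in zip(net.pods, exits):
            pod.exit = e
        object_update(net, eps=0.0)
        # windows: pod 0 at cols 0..3, pod 1 at cols 1..4 of a 2x5 buffer
        expected = np.zeros((2, 5), dtype=complex)
        counts = np.zeros((2, 5))
        expected[:, 0:4] += exits[0]
        counts[:, 0:4] += 1
        expected[:, 1:5] += exits[1]
        counts[:, 1:5] += 1
        expected /= counts
        np.testing.assert_allclose(
            net.containers["object"].storages["o0"].data[0], expected, atol=1e-12
        )

    def test_matches_brute_force_accumulation(self, rng):
        geom = Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=(2, 4))
        rp = geom.rpsize
        positions = np.array([[0.0, 0.0], [0.0, -rp[1]]])
        frames = FrameSet(frames=np.zeros((2, 2, 4)), masks=np.ones((1, 2, 4)),
                          geometry=geom)
        net = build_pods(ScanSpec(positions=positions, geometry=geom), frames)
        probes = rng.standard_normal((2, 2, 4)) + 1j * rng.standard_normal((2, 2, 4))
        exits = rng.standard_normal((2, 2, 4)) + 1j * rng.standard_normal((2, 2, 4))
        # both pods read the same probe storage layer: use one probe array
        net.containers["probe"].storages["p0"].data[0] = probes[0]
        for pod, e in zip(net.pods, exits):
            pod.exit = e
        object_update(net, eps=0.0)
        num = np.zeros((2, 5), dtype=complex)
        den = np.zeros((2, 5))
        for sl, e in zip((np.s_[:, 0:4], np.s_[:, 1:5]), exits):
            num[sl] += np.conj(probes[0]) * e
            den[sl] += np.abs(probes[0]) ** 2
        expected = num / den
        np.testing.assert_allclose(
            net.containers["object"].storages["o0"].data[0], expected, atol=1e-12
        )

    def test_probe_recovered_exactly_from_consistent_exits(self):
        _, frames, truth = small_scan(grid=(3, 3), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        storage = net.containers["probe"].storages["p0"]
        expected = storage.data.copy()
        storage.data[...] = -5.0 + 2j
        probe_update(net, eps=0.0)
        cov = net.containers["probe"].clone("cov").fill(0.0)
        for pod in net.pods:
            cov.window(pod.views["probe"])[...] += np.abs(pod.object) ** 2
        covered = cov.storages["p0"].data.real > 0
        scale = np.max(np.abs(expected))
        assert np.max(np.abs((storage.data - expected)[covered])) / scale < 1e-9

    def test_unit_object_gives_average_of_exits(self, rng):
        geom = Geometry(lam=650e-9, z=0.145, dpsize=72e-6, N=(2, 4))
        positions = np.zeros((2, 2))
        frames = FrameSet(frames=np.zeros((2, 2, 4)), masks=np.ones((1, 2, 4)),
                          geometry=geom)
        net = build_pods(ScanSpec(positions=positions, geometry=geom), frames)
        net.containers["object"].storages["o0"].data[...] = 1.0
        exits = rng.standard_normal((2, 2, 4)) + 1j * rng.standard_normal((2, 2, 4))
        for pod, e in zip(net.pods, exits):
            pod.exit = e
        probe_update(net, eps=0.0)
        np.testing.assert_allclose(
            net.containers["probe"].storages["p0"].data[0], exits.mean(axis=0),
            atol=1e-12,
        )


class TestIteration:
    def test_zero_iterations_change_nothing(self):
        _, frames, truth = small_scan(grid=(2, 2), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        snapshots = {
            e: {k: s.data.copy() for k, s in net.containers[e].storages.items()}
            for e in ("probe", "object", "exit")
        }
        engine = DMEngine(net, EngineParams(numiter=0, seed=1))
        trace = engine.iterate()
        assert len(trace) == 0
        for e, stores in snapshots.items():
            for k, data in stores.items():
                np.testing.assert_array_equal(net.containers[e].storages[k].data, data)

    def test_ground_truth_is_global_fixed_point(self):
        _, frames, truth = small_scan(grid=(3, 3), N=(16, 16))
        net = network_at_truth(frames, truth, frames.geometry)
        engine = DMEngine(net, EngineParams(numiter=5, probe_update_start=1, seed=1))
        trace = engine.iterate()
        assert all(c < 1e-9 for c in trace.exit_change)
        assert all(e < 1e-9 for e in trace.fourier_error)

    def test_error_drops_tenfold_on_synthetic_scan(self):
        config, frames, truth = small_scan(grid=(5, 5), N=(32, 32), seed=7)
        spec = ScanSpec(positions=truth["positions"], geometry=frames.geometry)
        net = build_pods(spec, frames)
        engine = DMEngine(net, EngineParams(numiter=50, seed=2))
        engine.initialize()
        trace = engine.iterate()
        assert len(trace) == 50
        assert min(trace.fourier_error) < trace.fourier_error[0] / 10.0

    def test_deterministic_given_seed(self):
        _, frames, truth = small_scan(grid=(2, 2), N=(16, 16))
        results = []
        for _ in range(2):
            spec = ScanSpec(positions=truth["positions"], geometry=frames.geometry)
            net = build_pods(spec, frames)
            engine = DMEngine(net, EngineParams(numiter=5, seed=42))
            engine.initialize()
            engine.iterate()
            results.append(net.containers["object"].storages["o0"].data.copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_masked_pixels_never_influence_reconstruction(self):
        """Perturbing diffraction data only where the mask is invalid
        yields bitwise-identical reconstructions."""
        _, frames, truth = small_scan(grid=(2, 2), N=(16, 16), dead_fraction=0.1)
        invalid = frames.masks[0] == 0
        assert invalid.sum() > 0
        outputs = []
        for perturb in (0.0, 7.5):
            f = frames.frames.copy()
            f[:, invalid] += perturb
            fs = FrameSet(frames=f, masks=frames.masks, geometry=frames.geometry)
            spec = ScanSpec(positions=truth["positions"], geometry=frames.geometry)
            net = build_pods(spec, fs)
            engine = DMEngine(net, EngineParams(numiter=4, seed=9))
            engine.initialize()
            engine.iterate()
            outputs.append(
                (
                    net.containers["object"].storages["o0"].data.copy(),
                    net.containers["probe"].storages["p0"].data.copy(),
                )
            )
        np.testing.assert_array_equal(outputs[0][0], outputs[1][0])
        np.testing.assert_array_equal(outputs[0][1], outputs[1][1])


class TestOrthogonalizeModes:
    def test_orthogonal_input_unchanged_up_to_phase(self):
        modes = np.zeros((2, 4, 4), dtype=complex)
        modes[0, 0, 0] = 2.0  # disjoint supports: already orthogonal
        modes[1, 1, 1] = 1.0
        rotated, fractions = orthogonalize_modes(modes)
        np.testing.assert_allclose(fractions, [0.8, 0.2], atol=1e-12)
        for out in rotated:
            matches = [
                np.max(np.abs(out - np.exp(1j * np.angle(np.vdot(m, out))) * m))
                for m in modes
            ]
            assert min(matches) < 1e-12

    def test_identical_modes_collapse_to_rank_one(self, rng):
        m = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        rotated, fractions = orthogonalize_modes(np.stack([m, m]))
        np.testing.assert_allclose(fractions, [1.0, 0.0], atol=1e-12)

    def test_random_modes_match_eigensolver_oracle(self, rng):
        modes = rng.standard_normal((3, 6, 6)) + 1j * rng.standard_normal((3, 6, 6))
        rotated, fractions = orthogonalize_modes(modes)
        flat = rotated.reshape(3, -1)
        G_out = flat @ flat.conj().T
        total = np.real(np.trace(G_out))
        off = G_out - np.diag(np.diag(G_out))
        assert np.max(np.abs(off)) < 1e-10 * total
        G_in = modes.reshape(3, -1) @ modes.reshape(3, -1).conj().T
        eigs = np.sort(np.linalg.eigvalsh(G_in))[::-1]
        np.testing.assert_allclose(fractions, eigs / eigs.sum(), atol=1e-12)
        assert abs(np.sum(np.abs(rotated) ** 2) - np.sum(np.abs(modes) ** 2)) < 1e-12 * total
        assert abs(fractions.sum() - 1.0) < 1e-12


class TestFixAmbiguities:
    def build(self):
        _, frames, truth = small_scan(grid=(3, 3), N=(16, 16))
        return network_at_truth(frames, truth, frames.geometry)

    def test_idempotent(self):
        net = self.build()
        fix_ambiguities(net)
        probe1 = net.containers["probe"].storages["p0"].data.copy()
        obj1 = net.containers["object"].storages["o0"].data.copy()
        scale = fix_ambiguities(net)
        assert abs(scale - 1.0) < 1e-12
        np.testing.assert_allclose(net.containers["probe"].storages["p0"].data,
                                   probe1, atol=1e-12 * np.max(np.abs(probe1)))
        np.testing.assert_allclose(net.containers["object"].storages["o0"].data,
                                   obj1, atol=1e-12)

    def test_gauge_invariance(self):
        a = 0.37 * np.exp(1j * 1.1)
        results = []
        for gauge in (1.0, a):
            net = self.build()
            net.containers["probe"].scale(gauge)
            net.containers["object"].scale(1.0 / gauge)
            fix_ambiguities(net)
            results.append(
                (
                    net.containers["probe"].storages["p0"].data.copy(),
                    net.containers["object"].storages["o0"].data.copy(),
                )
            )
        scale = np.max(np.abs(results[0][0]))
        assert np.max(np.abs(results[0][0] - results[1][0])) / scale < 1e-10
        assert np.max(np.abs(results[0][1] - results[1][1])) < 1e-10

    def test_model_intensities_unchanged(self):
        net = self.build()
        before = [model_intensity(net.pods_of_frame(j)) for j in net.frame_indices]
        fix_ambiguities(net)
        after = [model_intensity(net.pods_of_frame(j)) for j in net.frame_indices]
        for b, a in zip(before, after):
            assert np.max(np.abs(a - b)) < 1e-12 * np.max(b)

    def test_zero_probe_rejected(self):
        net = self.build()
        net.containers["probe"].fill(0.0)
        with pytest.raises(ValueError):
            fix_ambiguities(net)
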