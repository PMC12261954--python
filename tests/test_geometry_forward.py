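import numpy as np
import pytest

import vepforward as vf
from vepforward.geometry_forward import TopographySet

from conftest import upper_mask


class TestWedgeSet:
    @pytest.mark.parametrize(
        "n,inner,outer,width",
        [(16, 2.75, 7.25, 22.5), (4, 1.0, 2.0, 90.0), (8, 1.0, 5.0, 45.0)],
    )
    def test_tiling(self, n, inner, outer, width):
        ws = vf.build_wedge_set(n, inner, outer)
        assert len(ws) == n
        assert all(abs(w.polar_width - width) < 1e-12 for w in ws)
        assert abs(sum(w.polar_width for w in ws) - 360.0) < 1e-9
        # quadrant bookkeeping: n/4 per quadrant, ranks 1..n/4
        for q in range(4):
            ranks = sorted(w.vm_rank for w in ws if w.quadrant == q)
            assert ranks == list(range(1, n // 4 + 1))

    def test_non_divisible_count_rejected(self):
        with pytest.raises(ValueError):
            vf.build_wedge_set(6)
        with pytest.raises(ValueError):
            vf.build_wedge_set(16, 5.0, 2.0)

    def test_hemifields(self):
        ws = vf.build_wedge_set()
        assert all(
            (w.hemifield == "right") == (w.polar_center < 180) for w in ws
        )


class TestSurfaceNormal:
    def _cube(self):
        return np.mgrid[-2:3, -2:3, -2:3].reshape(3, -1).T.astype(float)

    def test_pure_gradient(self):
        g = self._cube()
        n = vf.surface_normal_from_voxels(g, 2.0 * g[:, 0])
        assert np.allclose(n, [1, 0, 0], atol=1e-12)

    def test_diagonal_gradient(self):
        g = self._cube()
        n = vf.surface_normal_from_voxels(g, g[:, 0] + g[:, 1])
        assert np.allclose(n, [np.sqrt(0.5), np.sqrt(0.5), 0], atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        g = self._cube()
        rng = np.random.default_rng(0)
        b = 3 * g[:, 0] - g[:, 1] + 0.5 * g[:, 2] + rng.normal(0, 0.1, len(g))
        n = vf.surface_normal_from_voxels(g, b)
        X = np.column_stack([np.ones(len(g)), g])
        beta = np.linalg.solve(X.T @ X, X.T @ b)
        oracle = beta[1:] / np.linalg.norm(beta[1:])
        assert np.abs(n - oracle).max() < 1e-9

    def test_constant_cube_rejected(self):
        g = self._cube()
        with pytest.raises(ValueError):
            vf.surface_normal_from_voxels(g, np.ones(len(g)))


class TestSphereProjection:
    def test_radial_dipole_peaks_under_electrode(self, layout):
        head = vf.SphereHeadModel()
        v = head.potential(
            np.array([0.0, 0.0, 0.07]), np.array([0.0, 0.0, 1.0]),
            layout.positions,
        )
        assert np.allclose(layout.positions[np.argmax(v)], [0, 0, 1])

    def test_rotational_symmetry(self, layout):
        head = vf.SphereHeadModel()
        v = head.potential(
            np.array([0.0, 0.0, 0.07]), np.array([0.0, 0.0, 1.0]),
            layout.positions,
        )
        # electrodes at equal polar angle from the axis see equal potential
        ring = np.isclose(layout.positions[:, 2], layout.positions[1, 2])
        assert np.ptp(v[ring]) < 1e-9 * np.abs(v).max()

    def test_centre_dipole_closed_form(self, layout):
        head = vf.SphereHeadModel()
        q = np.array([0.3, -0.2, 0.9])
        v = head.potential(np.zeros(3), q, layout.positions)
        exact = 3.0 * (layout.positions * head.radius) @ q / (
            4 * np.pi * head.conductivity * head.radius**3
        )
        assert np.abs(v - exact).max() < 1e-12 * np.abs(exact).max()

    def test_outside_head_rejected(self, layout):
        head = vf.SphereHeadModel()
        with pytest.raises(ValueError):
            head.potential(
                np.array([0.0, 0.0, 0.1]), np.array([0, 0, 1.0]),
                layout.positions,
            )

    def test_projection_linearity_and_reference(self, layout, wedges):
        head = vf.SphereHeadModel()
        patches = vf.synth_cortical_patches("V1", wedges)
        tset = vf.project_dipoles(patches, head, layout)
        # average reference
        assert np.abs(tset.values.mean(axis=1)).max() < 1e-12
        # mean-over-dipoles linearity: a patch of two dipoles equals the
        # mean of the single-dipole projections
        from vepforward.geometry_forward import DipolePatchSet

        p = patches.positions[0][:2]
        m = patches.moments[0][:2]
        both = vf.project_dipoles(
            DipolePatchSet("V1", [p], [m], wedges[:1]), head, layout
        )
        singles = [
            vf.project_dipoles(
                DipolePatchSet("V1", [p[i : i + 1]], [m[i : i + 1]], wedges[:1]),
                head, layout,
            )
            for i in range(2)
        ]
        mean_single = 0.5 * (singles[0].values + singles[1].values)
        assert np.abs(both.values - mean_single).max() < 1e-12


class TestCorticalPatches:
    @pytest.mark.parametrize("area", ["V1", "V2", "V3"])
    def test_patch_wellformed(self, area, wedges):
        ps = vf.synth_cortical_patches(area, wedges)
        for pos, mom in zip(ps.positions, ps.moments):
            assert len(pos) >= 1
            assert np.allclose(np.linalg.norm(mom, axis=1), 1.0, atol=1e-9)

    def test_unknown_area_rejected(self, wedges):
        with pytest.raises(ValueError):
            vf.synth_cortical_patches("V5", wedges)

    @staticmethod
    def _mirror_index(w, wedges):
        c = (180.0 - w.polar_center) % 360.0
        return next(
            x.index
            for x in wedges
            if abs(((x.polar_center - c + 180) % 360) - 180) < 1e-6
        )

    @pytest.mark.parametrize("area", ["V1", "V2", "V3"])
    def test_upper_lower_moments_opposed(self, area, wedges):
        """Polarity inversion across the horizontal meridian: mean
        moments of mirrored upper/lower wedges point oppositely."""
        ps = vf.synth_cortical_patches(area, wedges)
        for w in wedges:
            if not w.upper_field:
                continue
            dot = ps.mean_moment(w.index) @ ps.mean_moment(
                self._mirror_index(w, wedges)
            )
            assert dot < 0

    def test_v3_moments_constant_within_quadrant(self, wedges):
        ps = vf.synth_cortical_patches("V3", wedges)
        for q in range(4):
            idx = [w.index for w in wedges if w.quadrant == q]
            ms = np.array([ps.mean_moment(i) for i in idx])
            angles = np.degrees(
                np.arccos(np.clip(ms @ ms.T, -1, 1))
            )
            assert angles.max() < 10.0

    def test_v1_rotates_wall_to_sulcus(self, wedges):
        """Within a quadrant V1 moments rotate from lateral-axis
        (medial-wall) orientation at the vertical meridian towards
        vertical (sulcal) orientation at the horizontal meridian."""
        ps = vf.synth_cortical_patches("V1", wedges)
        for q in range(4):
            by_rank = sorted(
                (w for w in wedges if w.quadrant == q), key=lambda w: w.vm_rank
            )
            m1 = ps.mean_moment(by_rank[0].index)
            m4 = ps.mean_moment(by_rank[-1].index)
            assert abs(m1[0]) > abs(m4[0])  # more lateral-axis at VM
            assert abs(m4[2]) > abs(m1[2])  # more vertical at HM

    def test_v2_rotation_opposite_v1(self, wedges):
        """The within-quadrant rotation sense of V2 moments (in the
        medial/vertical plane of the source hemisphere) is opposite to
        V1's."""

        def senses(area):
            ps = vf.synth_cortical_patches(area, wedges)
            out = []
            for q in range(4):
                by_rank = sorted(
                    (w for w in wedges if w.quadrant == q),
                    key=lambda w: w.vm_rank,
                )
                hs = 1 if by_rank[0].hemifield == "left" else -1
                angs = []
                for w in by_rank:
                    m = ps.mean_moment(w.index)
                    angs.append(np.arctan2(m[2], -hs * m[0]))
                out.append(np.sign(np.unwrap(angs)[-1] - np.unwrap(angs)[0]))
            return out

        s1, s2 = senses("V1"), senses("V2")
        assert all(a * b < 0 for a, b in zip(s1, s2))


class TestPredictedTopographyStructure:
    """The laterality and correlation signatures that distinguish the
    three visual areas (the basis of the source-inference heuristics)."""

    def test_laterality_signature(self, predicted, wedges):
        ups = upper_mask(wedges)
        lat = {a: vf.laterality_index(predicted[a]) for a in predicted}
        assert np.all(lat["V1"].values[ups] > 0)
        assert np.all(lat["V1"].values[~ups] < 0)
        assert np.all(lat["V2"].values[ups] < 0)
        assert np.all(lat["V2"].values[~ups] > 0)
        m3 = np.abs(lat["V3"].values).mean()
        assert m3 < np.abs(lat["V1"].values).mean()
        assert m3 < np.abs(lat["V2"].values).mean()

    def test_within_quadrant_monotonicity(self, predicted, wedges):
        lat1 = vf.laterality_index(predicted["V1"]).values
        lat2 = vf.laterality_index(predicted["V2"]).values
        for q in range(4):
            by_rank = sorted(
                (w for w in wedges if w.quadrant == q), key=lambda w: w.vm_rank
            )
            idx = [w.index for w in by_rank]
            v1 = lat1[idx]
            v2 = lat2[idx]
            if by_rank[0].upper_field:
                assert np.all(np.diff(v1) < 0)  # most ipsilateral at the VM
                assert np.all(np.diff(v2) > 0)
            else:
                assert np.all(np.diff(v1) > 0)  # most contralateral at the VM
                assert np.all(np.diff(v2) < 0)

    def test_interarea_correlation_signs(self, predicted):
        r12 = vf.correlate_sets(predicted["V1"], predicted["V2"]).r_stacked
        r13 = vf.correlate_sets(predicted["V1"], predicted["V3"]).r_stacked
        assert r12 > 0
        assert r13 < 0


class TestTopographyIO:
    def test_round_trip(self, tmp_path, layout, wedges):
        rng = np.random.default_rng(0)
        tset = TopographySet("x", rng.normal(size=(16, 128)), layout, wedges)
        path = tmp_path / "topo.tsv"
        vf.write_topography_set(tset, path)
        back = vf.read_topography_set(path, layout, wedges)
        assert np.allclose(back.values, tset.values)
        assert back.values.size == 2048

    def test_missing_wedge_reported(self, tmp_path, layout, wedges):
        import pandas as pd

        tset = TopographySet("x", np.ones((16, 128)), layout, wedges)
        path = tmp_path / "topo.tsv"
        vf.write_topography_set(tset, path)
        df = pd.read_csv(path, sep="\t")
        df[df["wedge"] != 7].to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="7"):
            vf.read_topography_set(path, layout, wedges)


class TestElectrodeLayout:
    def test_invariants(self, layout):
        assert layout.n_electrodes == 128
        assert len(set(layout.ids)) == 128
        assert np.allclose(
            np.linalg.norm(layout.positions, axis=1), 1.0, atol=1e-9
        )
        order = np.argsort(layout.positions[:, 0])
        assert np.all(np.diff(layout.lateral_coord[order]) >= -1e-12)
        assert layout.lateral_coord.min() == -1.0
        assert layout.lateral_coord.max() == 1.0

    def test_mirror_symmetry(self, layout):
        idx = layout.mirrored_index()
        assert np.allclose(
            layout.positions[idx, 0], -layout.positions[:, 0], atol=1e-9
        )

    def test_layout_round_trip(self, tmp_path, layout):
        path = tmp_path / "layout.tsv"
        vf.write_layout(layout, path)
        back = vf.read_layout(path)
        assert back.ids == layout.ids
        assert np.allclose(back.positions, layout.positions)
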