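"""Population selection, exact histogramming, differential and free-energy maps."""

import numpy as np
import pytest

from preorg import synthetic as syn
from preorg.errors import ContractError, SelectionError
from preorg.geometry import DimerGeometry, enumerate_dimers
from preorg.maps import (
    ConformerHistogram,
    PopulationSelection,
    band_mass,
    default_axes,
    differential_map,
    dimer_table,
    free_energy_map,
    histogram3d,
    psi_marginal,
    select_populations,
)
from preorg.model import Ensemble, Frame


def _manual_frame(make_solute, solute_positions, modifier=None):
    mols = [make_solute(np.eye(3), p, i) for i, p in enumerate(solute_positions)]
    if modifier is not None:
        mols.append(syn.modifier_template(2).template.instantiate(np.eye(3), modifier, 99))
    return Frame(molecules=mols, frame_index=0)


class TestSelection:
    def test_straddle_rule(self, make_solute):
        # modifier at origin; A close (stacked 3.5 above its plane), B far but
        # within the pair radius of A
        frame = _manual_frame(
            make_solute, [(0, 0, 3.4), (0, 0, 7.4)], modifier=(0, 0, 0)
        )
        ens = Ensemble(frames=[frame])
        near, bulk = select_populations(ens, PopulationSelection())
        assert len(near) == 0 and len(bulk) == 0  # straddles: excluded from both
        near, bulk = select_populations(
            ens, PopulationSelection(membership_rule="either_member")
        )
        assert len(near) == 1 and len(bulk) == 0

    def test_both_near_and_both_far(self, make_solute):
        frame = _manual_frame(
            make_solute,
            [(0, 0, 3.4), (6.4, 0, 3.4), (30.0, 0, 0), (30.0, 0, 4.0)],
            modifier=(0, 0, 0),
        )
        near, bulk = select_populations(Ensemble(frames=[frame]))
        assert len(near) == 1 and len(bulk) == 1

    def test_conservation(self, templated_small):
        sel = PopulationSelection()
        near, bulk = select_populations(templated_small, sel)
        total = sum(
            len(enumerate_dimers(f, r_max=sel.r_max)) for f in templated_small
        )
        straddle = total - len(near) - len(bulk)
        assert straddle >= 0
        assert len(near) + len(bulk) + straddle == total

    def test_no_modifier_rejected(self, bulk_small):
        with pytest.raises(SelectionError):
            select_populations(bulk_small, require_modifier=True)


class TestHistogram:
    def test_single_bin(self):
        dimers = [DimerGeometry(r=4.05, theta=0.1, psi=0.1) for _ in range(4)]
        h = histogram3d(dimers)
        assert h.probability.max() == pytest.approx(1.0)
        assert h.total == 4

    def test_interior_edge_goes_to_upper_bin(self):
        axes = default_axes()
        g = DimerGeometry(r=4.0, theta=0.0, psi=0.0)  # r exactly on an edge
        h = histogram3d([g], axes)
        i = np.nonzero(h.counts)[0][0]
        assert axes["r"][i] == pytest.approx(4.0)  # lower edge of the hit bin

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(3)
        axes = default_axes()
        dimers = [
            DimerGeometry(
                r=rng.uniform(2.0, 8.0), theta=rng.uniform(0, np.pi), psi=rng.uniform(0, np.pi)
            )
            for _ in range(10_000)
        ]
        h = histogram3d(dimers, axes)
        ref = np.zeros_like(h.counts)
        edges = [axes[a] for a in ("r", "theta", "psi")]
        for g in dimers:
            idx = []
            for val, e in zip(g.params, edges):
                k = int(np.searchsorted(e, val, side="right")) - 1
                if val == e[-1]:
                    k -= 1  # last bin closed
                if not 0 <= k < len(e) - 1:
                    break
                idx.append(k)
            else:
                ref[tuple(idx)] += 1
        assert np.array_equal(h.counts, ref)

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            histogram3d([])

    def test_probability_sums_to_one(self, bulk_small):
        from preorg.maps import select_populations

        _, bulk = select_populations(bulk_small, require_modifier=False)
        h = histogram3d(bulk)
        assert h.probability.sum() == pytest.approx(1.0, abs=1e-12)


class TestDifferentialMap:
    def _hist(self, rng, n):
        return histogram3d(
            [
                DimerGeometry(
                    r=rng.uniform(2, 8), theta=rng.uniform(0, np.pi), psi=rng.uniform(0, np.pi)
                )
                for _ in range(n)
            ]
        )

    def test_identity_gives_zero(self):
        h = self._hist(np.random.default_rng(1), 500)
        d = differential_map(h, h, ("r", "psi"))
        assert np.allclose(d.values, 0.0)

    def test_antisymmetry_and_zero_sum(self):
        rng = np.random.default_rng(2)
        h1, h2 = self._hist(rng, 400), self._hist(rng, 700)
        d12 = differential_map(h1, h2, ("r", "psi"))
        d21 = differential_map(h2, h1, ("r", "psi"))
        assert np.allclose(d12.values, -d21.values)
        assert abs(d12.values.sum()) < 1e-9

    def test_mismatched_axes_rejected(self):
        h1 = self._hist(np.random.default_rng(1), 100)
        axes = default_axes()
        axes["r"] = np.arange(2.0, 8.0 + 1e-9, 0.4)
        h2 = histogram3d([DimerGeometry(r=4.0, theta=1.0, psi=1.0)], axes)
        with pytest.raises(ContractError):
            differential_map(h1, h2, ("r", "psi"))

    def test_axis_order_respected(self):
        h = self._hist(np.random.default_rng(4), 300)
        d_rp = differential_map(h, h, ("r", "psi"))
        assert d_rp.values.shape == (30, 36)
        d_pr = differential_map(h, h, ("psi", "r"))
        assert d_pr.values.shape == (36, 30)


class TestPsiMarginal:
    def test_noise_free_bulk_mass_at_ends(self):
        spec = syn.EnsembleSpec(
            n_frames=2, n_solutes=8, coplanar_fraction_bulk=0.0,
            angular_noise_sd=0.0, stack_distance_sd=0.0, seed=2,
        )
        dimers = []
        for f in syn.make_bulk_ensemble(spec):
            dimers.extend(enumerate_dimers(f))
        pm = psi_marginal(histogram3d(dimers))
        ends = pm.iloc[0] + pm.iloc[-1]
        assert ends == pytest.approx(1.0)

    def test_uniform_psi_flat_within_sampling_error(self):
        rng = np.random.default_rng(8)
        n = 50_000
        dimers = [
            DimerGeometry(r=4.0, theta=1.0, psi=rng.uniform(0, np.pi)) for _ in range(n)
        ]
        pm = psi_marginal(histogram3d(dimers))
        k = len(pm)
        se = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert np.all(np.abs(pm.values - 1 / k) <= 3.5 * se)

    def test_band_mass(self):
        dimers = [DimerGeometry(r=4.0, theta=0.0, psi=np.pi / 2) for _ in range(10)]
        pm = psi_marginal(histogram3d(dimers))
        assert band_mass(pm, np.pi / 2 - 0.3, np.pi / 2 + 0.3) == pytest.approx(1.0)


class TestFreeEnergyMap:
    def _hist_two_bins(self, p0: float):
        # weights realized as integer counts via a crafted observation list
        n0 = int(round(p0 * 1000))
        dimers = [DimerGeometry(r=2.1, theta=0.1, psi=0.1)] * n0 + [
            DimerGeometry(r=2.1, theta=0.1, psi=1.0)
        ] * (1000 - n0)
        return histogram3d(dimers)

    def test_equal_bins_are_zero(self):
        f = free_energy_map(self._hist_two_bins(0.5), ("r", "psi"))
        vals = f.values[np.isfinite(f.values)]
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_closed_form(self):
        p0 = np.exp(-1) / (1 + np.exp(-1))
        f = free_energy_map(self._hist_two_bins(p0), ("r", "psi"))
        vals = np.sort(f.values[np.isfinite(f.values)])
        # counts are rounded to integers, so match to the rounding error
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1] == pytest.approx(1.0, abs=5e-3)

    def test_argmin_is_probability_argmax(self):
        rng = np.random.default_rng(5)
        dimers = [
            DimerGeometry(
                r=rng.uniform(2, 8), theta=rng.uniform(0, np.pi), psi=rng.uniform(0, np.pi)
            )
            for _ in range(2000
            )
        ]
        h = histogram3d(dimers)
        f = free_energy_map(h, ("r", "theta"))
        p = h.marginal(("r", "theta"))
        masked = np.where(np.isnan(f.values), np.inf, f.values)
        assert np.unravel_index(np.argmin(masked), masked.shape) == np.unravel_index(
            np.argmax(p), p.shape
        )

    def test_empty_bins_masked_not_sentinel(self):
        h = self._hist_two_bins(0.5)
        f = free_energy_map(h, ("r", "psi"))
        assert np.isnan(f.values).sum() == f.values.size - 2


def test_dimer_table_columns(templated_small):
    near, _ = select_populations(templated_small)
    df = dimer_table(near)
    assert list(df.columns) == [
        "frame", "mol_a", "mol_b", "r", "theta", "psi", "class", "polarity",
    ]
    assert len(df) == len(near)
    assert set(df["class"]) <= {"stacked", "coplanar", "other"}
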