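"""Particle classification, concentrations and layer metrics."""

import numpy as np
import pytest

from plumezoo.plankton_metrics import (
    AbundanceProfile, LayerAbundance, ParticleRecord, classify_calanus,
    concentration_profile, layer_means, stage_shares, surface_ratio,
    weighted_mean_depth,
)


def _p(esd, ai, depth=10.0):
    return ParticleRecord("s", depth, esd, ai)


class TestClassifyCalanus:
    @pytest.mark.parametrize("esd,ai,kept", [
        (1.5, 0.6, True),
        (0.8, 0.9, False),    # below size window
        (2.6, 0.9, False),    # above size window
        (1.5, 0.40, False),   # AI boundary is strict
        (1.0, 0.41, True),    # ESD boundary is closed
        (2.5, 0.41, True),
    ])
    def test_selection_rule(self, esd, ai, kept):
        assert bool(classify_calanus([_p(esd, ai)])) is kept

    def test_subset_and_idempotent(self, rng):
        recs = [_p(float(e), float(a)) for e, a in
                zip(rng.uniform(0.3, 3, 200), rng.uniform(0, 1, 200))]
        kept = classify_calanus(recs)
        assert set(kept) <= set(recs)
        assert classify_calanus(kept) == kept

    def test_empty_in_empty_out(self):
        assert classify_calanus([]) == []


class TestConcentration:
    def test_division(self):
        prof = concentration_profile([12], [0.004], [5.5])
        assert prof.abundance[0] == pytest.approx(3000.0)

    def test_zero_counts(self):
        assert concentration_profile([0], [0.004], [5.5]).abundance[0] == 0.0

    def test_count_without_volume_errors(self):
        with pytest.raises(ValueError):
            concentration_profile([3], [0.0], [5.5])

    def test_poisson_recovery(self, rng):
        # counts ~ Poisson(lambda V) recover lambda within 3 SE
        lam, v, n = 800.0, 0.005, 1000
        counts = rng.poisson(lam * v, size=n)
        prof = concentration_profile(counts, np.full(n, v),
                                     1.5 + np.arange(n))
        se = np.sqrt(lam / v / n)
        assert abs(prof.abundance.mean() - lam) < 3 * se


class TestWMD:
    def test_uniform_is_grid_midpoint(self):
        z = np.arange(1.5, 50, 1.0)
        prof = AbundanceProfile("s", "Calanus", z, np.full(z.size, 5.0))
        assert weighted_mean_depth(prof) == pytest.approx(25.5)

    def test_point_mass(self):
        prof = AbundanceProfile("s", "Calanus", [10.5], [42.0])
        assert weighted_mean_depth(prof) == 10.5

    def test_hand_example(self):
        prof = AbundanceProfile("s", "Calanus", [10.0, 30.0], [3.0, 1.0])
        assert weighted_mean_depth(prof) == pytest.approx(15.0)

    def test_invariant_to_rescaling(self, rng):
        z = np.arange(1.5, 50, 1.0)
        a = rng.uniform(0, 10, z.size)
        p1 = AbundanceProfile("s", "x", z, a)
        p2 = AbundanceProfile("s", "x", z, 7.3 * a)
        assert weighted_mean_depth(p1) == pytest.approx(
            weighted_mean_depth(p2))

    def test_shape_ordering(self):
        # surface-peaked < uniform < bottom-peaked within 0-50 m
        z = np.arange(1.5, 50, 1.0)
        surf = AbundanceProfile("s", "x", z, np.exp(-z / 12))
        unif = AbundanceProfile("s", "x", z, np.ones(z.size))
        bot = AbundanceProfile("s", "x", z, np.exp(z / 12))
        assert (weighted_mean_depth(surf) < weighted_mean_depth(unif)
                < weighted_mean_depth(bot))

    def test_zero_abundance_flagged_nan(self):
        prof = AbundanceProfile("s", "x", [1.5, 2.5], [0.0, 0.0])
        assert np.isnan(weighted_mean_depth(prof))


class TestLayerMeans:
    def test_constant_profile(self):
        z = np.arange(1.5, 120, 1.0)
        out = layer_means(AbundanceProfile("s", "x", z, np.full(z.size, 100.0)))
        assert [la.abundance for la in out] == [100.0, 100.0, 100.0]

    def test_surface_only(self):
        z = np.arange(1.5, 120, 1.0)
        a = np.where(z < 10, 50.0, 0.0)
        out = layer_means(AbundanceProfile("s", "x", z, a))
        assert out[0].abundance > 0
        assert out[1].abundance == 0 and out[2].abundance == 0

    def test_matches_groupby_oracle(self, rng):
        z = np.arange(1.5, 200, 1.0)
        a = rng.uniform(0, 10, z.size)
        out = layer_means(AbundanceProfile("s", "x", z, a))
        oracle = [a[z <= 10].mean(), a[(z > 10) & (z <= 50)].mean(),
                  a[z > 50].mean()]
        np.testing.assert_allclose([la.abundance for la in out], oracle)

    def test_conserves_column_inventory(self, rng):
        # sum(layer mean x bins in layer) == depth-integrated abundance
        z = np.arange(1.5, 150, 1.0)
        a = rng.uniform(0, 10, z.size)
        out = layer_means(AbundanceProfile("s", "x", z, a))
        nbins = [np.sum(z <= 10), np.sum((z > 10) & (z <= 50)),
                 np.sum(z > 50)]
        total = sum(la.abundance * n for la, n in zip(out, nbins))
        assert total == pytest.approx(a.sum())


class TestNets:
    def test_surface_ratio(self):
        net = [LayerAbundance("0-10", "Calanus", 200.0),
               LayerAbundance("10-50", "Calanus", 100.0)]
        assert surface_ratio(net, "Calanus") == pytest.approx(2.0)

    def test_zero_numerator(self):
        net = [LayerAbundance("0-10", "Calanus", 0.0),
               LayerAbundance("10-50", "Calanus", 100.0)]
        assert surface_ratio(net, "Calanus") == 0.0

    def test_zero_denominator_flagged(self):
        net = [LayerAbundance("0-10", "Calanus", 100.0),
               LayerAbundance("10-50", "Calanus", 0.0)]
        assert np.isnan(surface_ratio(net, "Calanus"))

    def test_missing_layer_errors(self):
        with pytest.raises(ValueError):
            surface_ratio([LayerAbundance("0-10", "Calanus", 1.0)], "Calanus")

    def test_stage_shares_structure(self):
        net = [LayerAbundance("50-bottom", s, a) for s, a in
               [("CIV", 45.0), ("CV", 45.0), ("CI-CIII", 10.0)]]
        comp = stage_shares(net)[0]
        assert comp.shares["CIV"] + comp.shares["CV"] == pytest.approx(0.90)
        assert sum(comp.shares.values()) == pytest.approx(1.0)

    def test_single_stage(self):
        comp = stage_shares([LayerAbundance("0-10", "CV", 7.0)])[0]
        assert comp.shares == {"CV": 1.0}

    def test_normalization_oracle(self, rng):
        vals = rng.uniform(0.1, 5, 5)
        net = [LayerAbundance("10-50", s, float(v)) for s, v in
               zip(("nauplii", "CI-CIII", "CIV", "CV", "adult"), vals)]
        comp = stage_shares(net)[0]
        np.testing.assert_allclose(
            [comp.shares[s] for s, _ in zip(
                ("nauplii", "CI-CIII", "CIV", "CV", "adult"), vals)],
            vals / vals.sum())

    def test_all_zero_layer_errors(self):
        with pytest.raises(ValueError):
            stage_shares([LayerAbundance("0-10", "CV", 0.0)])
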