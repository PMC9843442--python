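"""The cone-scan statistic: profiles, methyl null, exceedance calls."""

import dataclasses

import numpy as np
import pytest

from chlassign.chlorin_frame import ConeGeometry
from chlassign.cone_scan import (
    ConeProfile,
    NullModel,
    ScanError,
    build_null,
    classify_formyl,
    scan_position,
)
from chlassign.density import DensityGrid, ScaleModel
from chlassign.fixtures import FixtureSpec, build_fixture, noise_sd_for_snr


def profile(values, position="C71", site="s"):
    n = len(values)
    return ConeProfile(site, position, np.arange(n) * (360.0 / n), np.asarray(values, float))


def test_flat_profile_on_constant_map(chla_bundle):
    site = chla_bundle.site
    grid = chla_bundle.grid
    const = DensityGrid(
        values=np.full(grid.shape, 3.0, dtype=np.float32),
        cell=grid.cell, origin=grid.origin, basis=grid.basis,
    )
    prof = scan_position(site, const, ConeGeometry("C21"), ScaleModel("none"))
    assert np.allclose(prof.values, 3.0)
    assert prof.peak_value == pytest.approx(3.0)
    assert prof.peak_angle_deg == 0.0  # ties resolve to the smallest angle


@pytest.mark.parametrize("dihedral", [0.0, 90.0, 215.0])
def test_scan_finds_formyl_at_generated_dihedral(dihedral):
    bundle = build_fixture(FixtureSpec(chl_type="f", formyl_dihedral_deg=dihedral, seed=21))
    prof = scan_position(bundle.site, bundle.grid, ConeGeometry("C21"), ScaleModel())
    delta = abs((prof.peak_angle_deg - dihedral + 180.0) % 360.0 - 180.0)
    assert delta <= 5.0  # within one angular step of the ground truth


def test_build_null_hand_arithmetic():
    null = build_null([profile([1.0, 1.0, 1.0, 3.0])])
    assert null.mu == pytest.approx(1.5)
    assert null.sigma == pytest.approx(1.0)  # sample SD, ddof=1
    assert null.threshold == pytest.approx(4.5)


def test_build_null_constant_values():
    null = build_null([profile([2.0] * 8)])
    assert null.mu == pytest.approx(2.0)
    assert null.sigma == 0.0
    assert null.threshold == pytest.approx(2.0)


@pytest.mark.parametrize("seed", range(5))
def test_threshold_is_exactly_mu_plus_three_sigma(seed):
    rng = np.random.default_rng(seed)
    null = build_null([profile(rng.normal(size=72)) for _ in range(3)])
    assert null.threshold - null.mu == pytest.approx(3.0 * null.sigma, rel=1e-12)


def test_build_null_input_validation():
    with pytest.raises(ScanError):
        build_null([])
    with pytest.raises(ScanError):
        build_null([profile([1.0, 2.0], position="C21")])


def test_classification_is_strict_exceedance():
    null = NullModel(mu=1.0, sigma=0.5, n_pooled=10)
    at = classify_formyl(profile([0.0, 2.5], position="C21"), null)
    assert at.call == "formyl_negative"  # equal to threshold does not exceed
    above = classify_formyl(profile([0.0, 2.6], position="C21"), null)
    assert above.call == "formyl_positive"
    assert above.threshold == pytest.approx(2.5)


def test_secondary_peaks_above_threshold_reported():
    """A two-orientation formyl shows two local maxima; both are evidence."""
    vals = np.zeros(72)
    vals[10] = 5.0
    vals[40] = 4.0
    vals[41] = 3.9
    v = classify_formyl(profile(vals, position="C21"), NullModel(0.0, 1.0, 72))
    angles = sorted(e["peak_angle_deg"] for e in v.evidence)
    assert angles == [50.0, 200.0]
    assert v.peak_angle_deg == 50.0


def test_methyl_site_negative_across_noise_seeds():
    """A methyl-only site stays scan-negative in >= 19/20 noise realizations.

    Noise emulates a well-resolved map region (atom peaks an order of
    magnitude above the voxel noise SD); the methyl null pools the site's
    C7 scans across the realizations, mirroring the pooled-null protocol.
    """
    base = FixtureSpec(chl_type="a")
    nsd = noise_sd_for_snr(base, 10.0)
    scale = ScaleModel()
    bundles = [
        build_fixture(dataclasses.replace(base, seed=seed, noise_sd=nsd))
        for seed in range(20)
    ]
    null = build_null(
        [scan_position(b.site, b.grid, ConeGeometry("C71"), scale) for b in bundles]
    )
    negatives = sum(
        classify_formyl(
            scan_position(b.site, b.grid, ConeGeometry("C21"), scale), null
        ).call
        == "formyl_negative"
        for b in bundles
    )
    assert negatives >= 19


def test_scan_error_when_cone_leaves_map(chlf_bundle):
    site, grid = chlf_bundle.site, chlf_bundle.grid
    cropped = DensityGrid(
        values=grid.values[:4], cell=grid.cell, origin=grid.origin, basis=grid.basis
    )
    with pytest.raises(ScanError, match=site.site_id):
        scan_position(site, cropped, ConeGeometry("C21"), ScaleModel("none"))


def test_verdict_invariant_under_positive_affine_map(chlf_bundle, chla_bundle):
    """With the default scaling, a*map+b with small b does not flip verdicts;
    with zscore_local the profiles are exactly invariant."""
    scale = ScaleModel("zscore_local")
    bundles = (chlf_bundle, chla_bundle)

    def verdicts(transform):
        grids = [
            DensityGrid(
                values=transform(b.grid.values),
                cell=b.grid.cell, origin=b.grid.origin, basis=b.grid.basis,
            )
            for b in bundles
        ]
        null = build_null(
            [scan_position(b.site, g, ConeGeometry("C71"), scale) for b, g in zip(bundles, grids)]
        )
        return [
            classify_formyl(scan_position(b.site, g, ConeGeometry("C21"), scale), null).call
            for b, g in zip(bundles, grids)
        ]

    assert verdicts(lambda v: v) == verdicts(lambda v: 2.5 * v + 1.0)


def test_error_rate_rises_as_snr_falls():
    """Monotone (within Monte-Carlo noise) degradation with noise level."""
    base = FixtureSpec()
    scale = ScaleModel()

    def errors(snr, n=15):
        nsd = noise_sd_for_snr(base, snr)
        wrong = 0
        for seed in range(n):
            specs = [
                dataclasses.replace(
                    base, chl_type=t, seed=1000 * seed + i, noise_sd=nsd,
                    formyl_dihedral_deg=float((seed * 53 + i * 91) % 360), random_pose=True,
                )
                for i, t in enumerate(["f", "a"])
            ]
            bundles = [build_fixture(s) for s in specs]
            null = build_null(
                [scan_position(b.site, b.grid, ConeGeometry("C71"), scale) for b in bundles]
            )
            for b in bundles:
                call = classify_formyl(
                    scan_position(b.site, b.grid, ConeGeometry("C21"), scale), null
                ).call
                want = "formyl_positive" if b.site.annotated_type == "f" else "formyl_negative"
                wrong += call != want
        return wrong

    assert errors(8.0) <= errors(1.0)
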