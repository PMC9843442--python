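"""Donor search, aromatic contacts, and the annotation benchmark."""

import dataclasses

import numpy as np
import pytest

from chlassign.fixtures import DonorSpec, FixtureSpec, build_fixture, make_environment
from chlassign.hbond_search import (
    HBondConfig,
    benchmark_structure,
    classify_site_hbond,
    detect_aromatic_contact,
    find_donors,
)
from chlassign.structure_io import AtomRecord
from tests.conftest import random_rotation

_HYDROXYL = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}


def brute_force_donors(site, atoms, cfg):
    """Oracle: plain double loop over atoms with inline class rules."""
    probe = site.atoms[cfg.probe_position]
    out = []
    for rec in atoms:
        if (
            rec.chain_id == site.chain_id
            and rec.residue_seq == site.residue_seq
            and rec.residue_name == site.ligand_code
        ):
            continue
        is_n = rec.element == "N" and not rec.is_hetero and "any_nitrogen" in cfg.donor_classes
        is_oh = (
            rec.element == "O"
            and (rec.residue_name, rec.atom_name) in _HYDROXYL
            and "hydroxyl_oxygen" in cfg.donor_classes
        )
        is_wat = (
            rec.element == "O"
            and rec.residue_name in ("HOH", "WAT", "DOD", "H2O")
            and "water_oxygen" in cfg.donor_classes
        )
        if not (is_n or is_oh or is_wat):
            continue
        d = float(np.sqrt(np.sum((rec.position - probe) ** 2)))
        if d <= cfg.cutoff:
            out.append((rec.chain_id, rec.residue_seq, rec.atom_name, round(d, 9)))
    return sorted(out, key=lambda t: t[3])


def as_tuples(hits):
    return [
        (h.donor.chain_id, h.donor.residue_seq, h.donor.atom_name, round(h.distance, 9))
        for h in hits
    ]


def donor_suite_spec(seed):
    """Seeded fixture with donors at randomized kinds/distances incl. boundary.

    Random directions are resampled (deterministically) until the placement
    clears the generator's 2 A clash guard.
    """
    from chlassign.fixtures import PlacementError, make_chl_site

    rng = np.random.default_rng(seed)
    kinds = ["hydroxyl", "sidechain_N", "backbone_N", "water"]
    donors = [
        DonorSpec("hydroxyl", 4.09, probe="C21", direction=(1, 0, 0)),
        DonorSpec("sidechain_N", 4.11, probe="C21", direction=(0, 0, 1)),
    ]
    base = FixtureSpec(chl_type="f", seed=seed)
    site, _, _ = make_chl_site(base)
    for _ in range(rng.integers(0, 4)):
        kind = kinds[int(rng.integers(0, 4))]
        dist = float(rng.uniform(2.6, 5.0))
        for _attempt in range(50):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = DonorSpec(kind, dist, probe="C21", direction=tuple(direction))
            try:
                make_environment(site, dataclasses.replace(base, donors=(candidate,)))
            except PlacementError:
                continue
            donors.append(candidate)
            break
    return dataclasses.replace(base, donors=tuple(donors))


def test_boundary_donors_inclusive_cutoff():
    bundle = build_fixture(donor_suite_spec(0), with_map=False)
    cfg = HBondConfig(cutoff=4.1, donor_classes=frozenset({"any_nitrogen", "hydroxyl_oxygen", "water_oxygen"}))
    hits = find_donors(bundle.site, bundle.atoms, cfg)
    dists = [round(h.distance, 3) for h in hits]
    assert 4.09 in dists  # included: 4.09 <= 4.1
    assert 4.11 not in dists  # excluded: 4.11 > 4.1


@pytest.mark.parametrize("seed", range(25))
def test_find_donors_matches_brute_force(seed):
    bundle = build_fixture(donor_suite_spec(seed), with_map=False)
    cfg = HBondConfig(
        donor_classes=frozenset({"any_nitrogen", "hydroxyl_oxygen", "water_oxygen"})
    )
    hits = find_donors(bundle.site, bundle.atoms, cfg)
    assert as_tuples(hits) == brute_force_donors(bundle.site, bundle.atoms, cfg)


def test_no_neighbors_gives_empty_list(chla_bundle):
    assert find_donors(chla_bundle.site, chla_bundle.atoms, HBondConfig()) == []


def test_missing_probe_atom_raises(chla_bundle):
    site = dataclasses.replace(chla_bundle.site)
    site.atoms = {k: v for k, v in site.atoms.items() if k != "C31"}
    with pytest.raises(KeyError, match="C31"):
        find_donors(site, chla_bundle.atoms, HBondConfig(probe_position="C31"))


def test_cutoff_monotonicity():
    bundle = build_fixture(donor_suite_spec(3), with_map=False)
    classes = frozenset({"any_nitrogen", "hydroxyl_oxygen", "water_oxygen"})
    previous = set()
    for cutoff in (2.5, 3.0, 3.5, 4.1, 5.0, 6.0):
        cfg = HBondConfig(cutoff=cutoff, donor_classes=classes)
        current = set(as_tuples(find_donors(bundle.site, bundle.atoms, cfg)))
        assert previous <= current  # enlarging the cutoff never removes a hit
        previous = current


def test_waters_excluded_by_default():
    spec = FixtureSpec(
        chl_type="f", seed=4, donors=(DonorSpec("water", 3.0, probe="C21"),)
    )
    bundle = build_fixture(spec, with_map=False)
    assert find_donors(bundle.site, bundle.atoms, HBondConfig()) == []
    with_water = HBondConfig(
        donor_classes=frozenset({"any_nitrogen", "hydroxyl_oxygen", "water_oxygen"})
    )
    hits = find_donors(bundle.site, bundle.atoms, with_water)
    assert [h.donor_class for h in hits] == ["water_O"]


def test_exclude_engaged_drops_busy_donor():
    """A donor with its own nearby acceptor is not available to the formyl."""
    spec = FixtureSpec(
        chl_type="f",
        seed=5,
        donors=(
            DonorSpec("hydroxyl", 3.2, probe="C21", direction=(1, 0, 0)),
            # competing acceptor 2.8 A from that hydroxyl (6.0 - 3.2 = 2.8)
            DonorSpec("water", 6.0, probe="C21", direction=(1, 0, 0)),
        ),
    )
    bundle = build_fixture(spec, with_map=False)
    plain = find_donors(bundle.site, bundle.atoms, HBondConfig())
    assert len(plain) == 1
    filtered = find_donors(bundle.site, bundle.atoms, HBondConfig(exclude_engaged=True))
    assert filtered == []


def test_classify_requires_hit():
    bundle = build_fixture(donor_suite_spec(1), with_map=False)
    cfg = HBondConfig()
    hits = find_donors(bundle.site, bundle.atoms, cfg)
    v = classify_site_hbond(bundle.site, hits, cfg)
    assert v.call == "formyl_positive"
    assert v.n_hits == len(hits)
    assert v.min_distance_A == pytest.approx(min(h.distance for h in hits))
    empty = classify_site_hbond(bundle.site, [], cfg)
    assert empty.call == "formyl_negative"


def test_verdict_invariant_under_rigid_motion():
    bundle = build_fixture(donor_suite_spec(7), with_map=False)
    cfg = HBondConfig()
    before = classify_site_hbond(bundle.site, find_donors(bundle.site, bundle.atoms, cfg), cfg)
    rng = np.random.default_rng(8)
    rot = random_rotation(rng)
    shift = rng.normal(size=3) * 15
    moved_site = bundle.site.transformed(rot, shift)
    moved_atoms = [
        dataclasses.replace(a, position=rot @ a.position + shift) for a in bundle.atoms
    ]
    after = classify_site_hbond(
        moved_site, find_donors(moved_site, moved_atoms, cfg), cfg
    )
    assert before.call == after.call
    assert before.n_hits == after.n_hits
    assert before.min_distance_A == pytest.approx(after.min_distance_A, abs=1e-9)


def test_in_plane_ring_is_ch_o_contact():
    spec = FixtureSpec(
        chl_type="f", seed=9,
        donors=(DonorSpec("phe_ring", 3.4, probe="C21", orientation="in_plane"),),
    )
    bundle = build_fixture(spec, with_map=False)
    contacts = detect_aromatic_contact(bundle.site, bundle.atoms, "C21")
    assert len(contacts) == 1
    c = contacts[0]
    assert c.contact_class == "CH_O"
    assert c.distance_to_ring_atom == pytest.approx(3.4, abs=1e-6)
    assert c.out_of_plane_deg == pytest.approx(0.0, abs=1e-6)


def test_axial_ring_is_cho_pi_contact():
    spec = FixtureSpec(
        chl_type="f", seed=10,
        donors=(DonorSpec("phe_ring", 3.0, probe="C21", orientation="axial"),),
    )
    bundle = build_fixture(spec, with_map=False)
    contacts = detect_aromatic_contact(bundle.site, bundle.atoms, "C21")
    assert [c.contact_class for c in contacts] == ["CHO_pi"]
    assert contacts[0].out_of_plane_deg == pytest.approx(90.0, abs=1e-6)


def test_no_ring_nearby_gives_no_contact(chla_bundle):
    assert detect_aromatic_contact(chla_bundle.site, chla_bundle.atoms, "C21") == []


def test_benchmark_all_chla_no_donors_is_perfect():
    bundles = [build_fixture(FixtureSpec(chl_type="a", seed=s, residue_seq=601 + s), with_map=False) for s in range(5)]
    atoms = [a for b in bundles for a in b.atoms]
    result = benchmark_structure([b.site for b in bundles], atoms, HBondConfig())
    assert (result.n_sites, result.n_correct, result.percent) == (5, 5, 100)


def test_benchmark_donor_iff_formyl_is_perfect_all_positions():
    """Clean truth-table suite: every probe position scores 100%."""
    for probe, formyl_type in (("C21", "f"), ("C31", "d"), ("C71", "b")):
        bundles = []
        for s in range(6):
            t = formyl_type if s % 2 == 0 else "a"
            donors = (DonorSpec("hydroxyl", 3.0, probe=probe),) if t != "a" else ()
            bundles.append(
                build_fixture(
                    FixtureSpec(chl_type=t, seed=40 + s, residue_seq=601 + s,
                                donors=donors, offset=(30.0 * s, 0.0, 0.0)),
                    with_map=False,
                )
            )
        atoms = [a for b in bundles for a in b.atoms]
        result = benchmark_structure(
            [b.site for b in bundles], atoms, HBondConfig(probe_position=probe)
        )
        assert result.percent == 100, f"probe {probe}"


def test_benchmark_counts_misannotation():
    """One donor-less formyl site -> one error, percent rounds correctly."""
    bundles = [
        build_fixture(
            FixtureSpec(chl_type="f", seed=50, residue_seq=601), with_map=False
        ),  # f without donor -> predicted a (wrong)
        build_fixture(FixtureSpec(chl_type="a", seed=51, residue_seq=602), with_map=False),
        build_fixture(FixtureSpec(chl_type="a", seed=52, residue_seq=603), with_map=False),
    ]
    atoms = [a for b in bundles for a in b.atoms]
    result = benchmark_structure([b.site for b in bundles], atoms, HBondConfig())
    assert (result.n_correct, result.percent) == (2, 67)


def test_benchmark_requires_annotations(chla_bundle):
    site = dataclasses.replace(chla_bundle.site)
    site.annotated_type = "unknown"
    with pytest.raises(ValueError):
        benchmark_structure([site], chla_bundle.atoms, HBondConfig())
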