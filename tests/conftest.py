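import dataclasses

import numpy as np
import pytest

from chlassign.fixtures import DonorSpec, FixtureSpec, build_fixture


@pytest.fixture(scope="session")
def chlf_bundle():
    """Chl f site (formyl at dihedral 90) with a hydroxyl donor and a map."""
    spec = FixtureSpec(
        chl_type="f",
        formyl_dihedral_deg=90.0,
        donors=(DonorSpec("hydroxyl", 3.0, probe="C21"),),
        seed=11,
    )
    return build_fixture(spec)


@pytest.fixture(scope="session")
def chla_bundle():
    """Plain Chl a site, no donors, with a map."""
    return build_fixture(FixtureSpec(chl_type="a", seed=12))


def suite_specs(n_formyl, n_methyl, seed0, noise_sd=0.0, random_pose=True):
    """Deterministic mixed formyl/methyl suite; dihedrals spread over 360."""
    base = FixtureSpec()
    return [
        dataclasses.replace(
            base,
            chl_type="f" if i < n_formyl else "a",
            seed=seed0 + i,
            noise_sd=noise_sd,
            formyl_dihedral_deg=float((seed0 * 13 + i * 97) % 360),
            random_pose=random_pose,
        )
        for i in range(n_formyl + n_methyl)
    ]


def random_rotation(rng):
    """Uniform random rotation matrix (QR-based, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
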