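"""Combined-evidence assignment: H-bond search + cone scan, OR-combined.

The two evidence channels are complementary: the donor search needs only
coordinates and catches formyl sites with classical donors; the cone scan
needs a map and catches formyl density directly (including donor-less
sites), but fails where local resolution is poor.  The combined call is a
logical OR of the channels — each channel is still reported separately so
a user can weigh them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .chlorin_frame import ConeGeometry
from .cone_scan import NullModel, ScanError, build_null, classify_formyl, scan_position
from .density import DensityGrid, ScaleModel
from .hbond_search import HBondConfig, classify_site_hbond, detect_aromatic_contact, find_donors
from .structure_io import AtomRecord, ChlSite, SiteVerdict

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CombinedReport", "run_combined"]


@dataclass
class RunConfig:
    """Everything that determines a run; serialized beside every output."""

    structure: Optional[str] = None
    density_map: Optional[str] = None
    probe_position: str = "C21"
    hbond: HBondConfig = field(default_factory=HBondConfig)
    step_deg: float = 5.0
    bond_len_CO: float = 1.22
    angle_CCO_deg: float = 120.0
    scale_mode: str = "macrocycle_mean"
    aromatic: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["hbond"]["donor_classes"] = sorted(self.hbond.donor_classes)
        return json.dumps(d, indent=1)

    def write_sidecar(self, out_path: str | Path) -> Path:
        side = Path(str(out_path) + ".config.json")
        side.write_text(self.to_json())
        return side


@dataclass
class CombinedReport:
    verdicts: list  # SiteVerdicts: per channel plus one combined per site
    null: Optional[NullModel] = None

    def combined(self) -> list:
        return [v for v in self.verdicts if v.method == "combined"]


def run_combined(
    sites: Sequence[ChlSite],
    atoms: Sequence[AtomRecord],
    grid: Optional[DensityGrid] = None,
    config: Optional[RunConfig] = None,
) -> CombinedReport:
    """Run both evidence channels over the sites and OR their calls.

    Without a map only the H-bond channel runs (scan fields stay empty).
    Sites with incomplete macrocycles are excluded from the scan channel
    (and from the pooled null) with a logged warning.
    """
    if config is None:
        config = RunConfig()
    cfg = dataclasses.replace(config.hbond, probe_position=config.probe_position)
    verdicts: list[SiteVerdict] = []
    scan_by_site: dict[str, SiteVerdict] = {}
    hb_by_site: dict[str, SiteVerdict] = {}
    aromatic_by_site: dict[str, list] = {}

    for site in sites:
        if config.probe_position not in site.atoms:
            logger.warning(
                "site %s: probe %s missing, site skipped", site.site_id, config.probe_position
            )
            continue
        hits = find_donors(site, atoms, cfg)
        v = classify_site_hbond(site, hits, cfg)
        hb_by_site[site.site_id] = v
        verdicts.append(v)
        if config.aromatic:
            aromatic_by_site[site.site_id] = detect_aromatic_contact(
                site, atoms, probe_position=config.probe_position
            )

    null = None
    if grid is not None:
        scale = ScaleModel(mode=config.scale_mode)
        scannable = [s for s in sites if s.complete]
        for s in sites:
            if not s.complete:
                logger.warning("site %s: incomplete macrocycle, excluded from scans", s.site_id)
        c7_profiles = []
        for site in scannable:
            try:
                c7_profiles.append(
                    scan_position(
                        site,
                        grid,
                        ConeGeometry(
                            "C71", config.step_deg, config.bond_len_CO, config.angle_CCO_deg
                        ),
                        scale,
                    )
                )
            except ScanError as exc:
                logger.warning("C7 scan failed: %s", exc)
        if c7_profiles:
            null = build_null(c7_profiles)
            for site in scannable:
                try:
                    profile = scan_position(
                        site,
                        grid,
                        ConeGeometry(
                            config.probe_position,
                            config.step_deg,
                            config.bond_len_CO,
                            config.angle_CCO_deg,
                        ),
                        scale,
                    )
                except ScanError as exc:
                    logger.warning("scan failed: %s", exc)
                    continue
                v = classify_formyl(profile, null)
                v.annotated_type = site.annotated_type
                v.ligand_code = site.ligand_code
                scan_by_site[site.site_id] = v
                verdicts.append(v)

    for site in sites:
        channels = [
            c
            for c in (hb_by_site.get(site.site_id), scan_by_site.get(site.site_id))
            if c is not None
        ]
        if not channels:
            continue
        arom = aromatic_by_site.get(site.site_id, [])
        positive = any(c.call == "formyl_positive" for c in channels)
        combined = SiteVerdict(
            site_id=site.site_id,
            method="combined",
            position_probed=config.probe_position,
            call="formyl_positive" if positive else "formyl_negative",
            evidence=[{"channel": c.method, "call": c.call} for c in channels]
            + [{"channel": "aromatic", "contacts": len(arom)}] * bool(arom),
            annotated_type=site.annotated_type,
            ligand_code=site.ligand_code,
            n_hits=hb_by_site[site.site_id].n_hits if site.site_id in hb_by_site else None,
            min_distance_A=(
                hb_by_site[site.site_id].min_distance_A if site.site_id in hb_by_site else None
            ),
            peak_angle_deg=(
                scan_by_site[site.site_id].peak_angle_deg if site.site_id in scan_by_site else None
            ),
            peak_value=(
                scan_by_site[site.site_id].peak_value if site.site_id in scan_by_site else None
            ),
            threshold=(
                scan_by_site[site.site_id].threshold if site.site_id in scan_by_site else None
            ),
        )
        verdicts.append(combined)
    return CombinedReport(verdicts=verdicts, null=null)
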