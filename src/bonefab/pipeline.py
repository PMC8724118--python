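"""End-to-end orchestration: per-sample analysis, cohort studies and the
voxel-size sensitivity experiment.

A sample run composes morphometry -> fabric measurement -> homogenization and
returns one flat record with every per-sample quantity; a cohort run stacks
records into a table, fits the power laws E, G ~ a (BV/TV)^b per principal
direction and the surface-fraction model, and archives results together with
the exact configuration (including the elasticity constants used) for audit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fabric as fab
from . import homogenization as hz
from . import morphometry as morph
from .io import degrade_voxel_size
from .stats import cohort_descriptives, fit_power_law, fit_surface_model, group_summaries
from .volume import BinaryVolume

MODULUS_COLUMNS = ("E_x_gpa", "E_y_gpa", "E_z_gpa", "G_yz_gpa", "G_xz_gpa", "G_xy_gpa")
DESCRIPTIVE_COLUMNS = (
    "bv_tv",
    "bs_tv",
    "tb_th_um",
    "tb_sp_um",
    "ef",
    "conn_d",
    "da",
    "d1",
    "d2",
    "d3",
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into every results bundle."""

    n_mil_directions: int = 5000
    mil_line_spacing: float = 1.0
    mil_step: float = 0.5
    mil_method: str = "fibonacci"
    seed: int = 0
    constants_profile: str = "printed"  # profile name or a JSON file path
    with_ef: bool = True
    n_ef_seeds: int = 64
    sensitivity_factors: tuple[int, ...] = (1, 2, 3, 4)
    output_dir: Optional[str] = None

    def constants(self) -> hz.KabelConstants:
        if self.constants_profile in ("printed", "calibrated"):
            return hz.KabelConstants.profile(self.constants_profile)
        return hz.KabelConstants.from_json(self.constants_profile)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sensitivity_factors"] = list(self.sensitivity_factors)
        return d


def analyze_sample(vol: BinaryVolume, cfg: Optional[RunConfig] = None) -> dict:
    """Full per-sample analysis; stage errors are captured, not raised.

    Returns a flat record with morphometry, fabric and elasticity entries
    (Table-style units).  Elasticity is reported in the fabric eigenbasis
    (x', y', z'), z' being the stiffest axis; the eigenvector matrix needed
    to rotate it into the volume axes is part of the record.
    """
    cfg = cfg or RunConfig()
    rec: dict = {
        "label": vol.label,
        "level": vol.level,
        "region": vol.region,
        "voxel_size_um": vol.voxel_size_um,
        "error": None,
    }
    try:
        m = morph.analyze_morphometry(
            vol, with_ef=cfg.with_ef, n_ef_seeds=cfg.n_ef_seeds, seed=cfg.seed
        )
        rec.update(m.as_record())
    except Exception as err:
        rec["error"] = f"morphometry: {err}"
        return rec
    try:
        fr = fab.measure_fabric(
            vol,
            n_directions=cfg.n_mil_directions,
            line_spacing=cfg.mil_line_spacing,
            seed=cfg.seed,
            step=cfg.mil_step,
            method=cfg.mil_method,
        )
        rec.update(fr.as_record())
        rec["eigenvectors"] = fr.eigenvectors.tolist()
    except Exception as err:
        rec["error"] = f"fabric: {err}"
        return rec
    try:
        elast = hz.assemble_stiffness(fr.lam, rec["bv_tv"], cfg.constants())
        if elast.valid:
            hz.engineering_constants(elast)
        rec.update(elast.as_record())
        if not elast.valid:
            rec["error"] = "homogenization: non-positive-definite stiffness"
    except Exception as err:
        rec["error"] = f"homogenization: {err}"
    return rec


@dataclass
class CohortResult:
    """Cohort table plus fits and summary statistics."""

    table: pd.DataFrame
    power_law_fits: dict
    surface_model: Optional[dict]
    descriptives: pd.DataFrame
    config: dict
    constants: dict
    notices: list = field(default_factory=list)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.table.drop(columns=["eigenvectors"], errors="ignore")
        table.to_csv(out / "cohort.csv", index=False)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        fits = {k: v for k, v in self.power_law_fits.items()}
        bundle = {
            "config": self.config,
            "constants": self.constants,
            "power_law_fits": fits,
            "surface_model": self.surface_model,
            "notices": self.notices,
        }
        (out / "fits.json").write_text(json.dumps(bundle, indent=2))
        return out


def run_cohort(
    volumes: Sequence[BinaryVolume],
    cfg: Optional[RunConfig] = None,
) -> CohortResult:
    """Analyze every volume and fit the cohort-level relationships.

    Per-direction power laws ``y = a x^b`` are fitted for the three Young's
    and three shear moduli against BV/TV over samples with valid elasticity;
    fits are skipped (with a notice) below three usable samples.
    """
    cfg = cfg or RunConfig()
    labels = [v.label for v in volumes]
    if len(labels) != len(set(labels)):
        dupes = {l for l in labels if labels.count(l) > 1}
        raise ValueError(f"duplicate sample labels: {sorted(map(str, dupes))}")
    records = [analyze_sample(v, cfg) for v in volumes]
    table = pd.DataFrame(records)
    notices = []
    fits: dict = {}
    ok = table[table["error"].isna()] if "error" in table else table
    for col in MODULUS_COLUMNS:
        if col not in ok.columns:
            continue
        sub = ok[["bv_tv", col]].dropna()
        if len(sub) < 3:
            notices.append(f"power-law fit skipped for {col}: only {len(sub)} usable samples")
            continue
        fits[col] = fit_power_law(sub["bv_tv"].to_numpy(), sub[col].to_numpy()).as_dict()
    surface = None
    if {"bv_tv", "bs_tv"} <= set(ok.columns):
        sub = ok[["bv_tv", "bs_tv"]].dropna()
        if len(sub) >= 2:
            k, r2 = fit_surface_model(sub["bv_tv"].to_numpy(), sub["bs_tv"].to_numpy())
            surface = {"K": k, "r_squared": r2, "n": int(len(sub))}
        else:
            notices.append("surface-model fit skipped: fewer than 2 usable samples")
    descr = cohort_descriptives(ok, [c for c in DESCRIPTIVE_COLUMNS if c in ok.columns])
    constants = cfg.constants()
    result = CohortResult(
        table=table,
        power_law_fits=fits,
        surface_model=surface,
        descriptives=descr,
        config=cfg.as_dict(),
        constants={
            "name": constants.name,
            "k_a": constants.k_a.tolist(),
            "k_b": constants.k_b.tolist(),
            "p": constants.p,
            "Et_GPa": constants.tissue_modulus_gpa,
        },
        notices=notices,
    )
    if cfg.output_dir:
        result.save(cfg.output_dir)
    return result


def summarize_by(result: CohortResult, by: str) -> pd.DataFrame:
    """Grouped descriptives of a cohort table (by level, region, ...)."""
    return group_summaries(result.table, by=by)


def voxel_sensitivity(
    vol: BinaryVolume,
    factors: Sequence[int] = (1, 2, 3, 4),
    cfg: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Re-analyze a volume at coarsened voxel sizes; normalize moduli to factor 1.

    Emulates the resolution error study: the finest grid is degraded by each
    integer factor, the full analysis re-run, and every modulus reported both
    absolute and normalized to its factor-1 value.
    """
    cfg = cfg or RunConfig()
    factors = sorted(set(int(f) for f in factors))
    if factors[0] < 1:
        raise ValueError("factors must be >= 1")
    if 1 not in factors:
        factors = [1] + factors
    if min(vol.shape) // max(factors) < 16:
        raise ValueError(
            f"coarsest factor {max(factors)} leaves fewer than 16 voxels per axis "
            f"of {vol.shape}"
        )
    rows = []
    for f in factors:
        dv = degrade_voxel_size(vol, f)
        rec = analyze_sample(dv, cfg)
        rec["factor"] = f
        rec["voxel_size_um_out"] = dv.voxel_size_um
        rows.append(rec)
    table = pd.DataFrame(rows)
    base = table[table["factor"] == 1].iloc[0]
    for col in MODULUS_COLUMNS:
        if col in table.columns and pd.notna(base.get(col)) and base[col] != 0:
            table[col.replace("_gpa", "_normalized")] = table[col] / base[col]
    return table
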