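"""End-to-end study pipeline: phantoms -> sections -> counts -> estimates -> stats.

Runs a complete synthetic four-group study (normoxia N, hypoxia H,
hypoxia+MitoQ HM, normoxia+MitoQ NM).  Each litter contributes one male
placenta to stereology (mirroring the one-placenta-per-litter,
males-only sampling rule of the study design); per-placenta stereology
follows the two-magnification scheme: low-power SUR sections for the
Cavalieri volume and zone fractions, and a high-power window on the
section nearest the placental midline for labyrinth vascular densities,
surfaces and membrane thickness.  Blot densitometry and immunostain OD
are simulated per dam and quantified, and the configured statistics
(two-factor GLM at dam level, litter-nested LMM at fetus level) close the
loop.

Every stage writes its outputs before the next starts, and a RunManifest
records the config hash, seeds and output digests; re-running with
``resume=True`` skips stages whose recorded outputs are unchanged.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .densitometry import calibrate_od, combine_exposures, measure_region_od, \
    normalize_expression
from .io import file_digest, write_json
from .phantom import GROUPS, LABELS, ZONE_OF, StudySynthSpec, group_factors, \
    make_placenta_phantom, make_step_tablet, synth_blot_fixture, \
    synth_study_table
from .probes import GridSpec, orthogonal_intercepts, overlay_cycloid_grid, \
    overlay_point_grid
from .sectioning import SectionImage, section_phantom
from .stats import glm_two_factor, lmm_litter
from .stereology import INTERCEPT_CORRECTION, KROGH_K_O2, cavalieri_volume, \
    absolute_volume, diffusion_capacity, harmonic_mean_thickness, \
    placental_efficiency, specific_diffusion_capacity, surface_area, \
    volume_fraction
from .units import Quantity

log = logging.getLogger("stereoplacenta")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "simulate_study",
           "estimate_power", "analyze_placenta", "default_config",
           "StageError"]

ZONE_NAMES = ("decidua", "junctional", "labyrinth")


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage name and offending input."""

    def __init__(self, stage: str, config_hash: str, message: str,
                 path: str | None = None):
        self.stage = stage
        self.path = path
        super().__init__(
            f"stage {stage!r} failed (config {config_hash[:12]})"
            + (f" on {path}" if path else "") + f": {message}")


def default_config() -> dict:
    """Study-condition defaults for the four-group phantom study."""
    return {
        "phantom": {
            "zone_fractions": [0.15, 0.30, 0.55],
            "semi_axes": [1250.0, 1250.0, 650.0],
            "n_capillaries": 180,
            "capillary_radius": 14.0,
            "n_channels": 130,
            "channel_radius": 16.0,
            "tau_true": 5.0,
        },
        "sampling": {
            "n_sections": 10,          # SUR sections per placenta
            "t_sec": 7.0,              # physical section thickness, µm
            "lowmag_pixel": 25.0,      # µm/px, whole-placenta sections
            "point_spacing": 100.0,    # µm, Cavalieri/zone point grid
            "highmag_pixel": 2.0,      # µm/px, labyrinth window
            "highmag_halfwidth": 300.0,  # µm, half-width in y of the window
            "fine_point_spacing": 25.0,
            "cycloid_spacing": 25.0,
            "line_spacing": 25.0,      # orthogonal-intercept start lines
        },
        "estimators": {
            "intercept_correction": INTERCEPT_CORRECTION,
            "krogh_K": KROGH_K_O2,
        },
        "study": {
            "litters_per_group": {"N": 16, "H": 16, "HM": 18, "NM": 16},
            "fetuses_per_litter": 8,
            "male_only": True,
            "one_placenta_per_litter": True,
            # group-level multiplicative effects on phantom generation
            "volume_effect": {"N": 1.0, "H": 1.14, "HM": 1.14, "NM": 1.0},
            "capillary_effect": {"N": 1.0, "H": 1.20, "HM": 1.20, "NM": 1.0},
            "channel_effect": {"N": 1.0, "H": 1.0, "HM": 1.15, "NM": 1.0},
            "litter_cv": 0.08,         # between-litter CV on placental scale
            "bw_mean_g": 3.63,
            "bw_sigma_litter": 0.18,   # g, between-litter SD of body weight
            "bw_sigma_resid": 0.25,    # g, within-litter SD
            "pw_density_g_per_cm3": 1.05,
        },
        "densitometry": {
            "expression_effect": {"N": 1.0, "H": 1.8, "HM": 1.25, "NM": 1.0},
            "expression_cv": 0.20,
            "actin_mean": 1000.0,
            "exposure_gains": [1.0, 2.0, 4.0],
            "noise_sd": 0.01,
            "saturation": 65535.0,
            "od_mean": {"N": 0.23, "H": 0.29, "HM": 0.24, "NM": 0.21},
            "od_cv": 0.10,
            "n_fields": 10,
        },
        "stats": {"control_group": "N"},
    }


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration with a content hash."""

    phantom: dict = field(default_factory=lambda: default_config()["phantom"])
    sampling: dict = field(default_factory=lambda: default_config()["sampling"])
    estimators: dict = field(default_factory=lambda: default_config()["estimators"])
    study: dict = field(default_factory=lambda: default_config()["study"])
    densitometry: dict = field(default_factory=lambda: default_config()["densitometry"])
    stats: dict = field(default_factory=lambda: default_config()["stats"])
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        base = default_config()
        kwargs = {}
        for name in ("phantom", "sampling", "estimators", "study",
                     "densitometry", "stats"):
            merged = copy.deepcopy(base[name])
            merged.update(d.get(name, {}))
            kwargs[name] = merged
        kwargs["seed"] = int(d.get("seed", 0))
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            d = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ValueError(f"invalid config YAML at {path}: {e}") from e
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.sampling["n_sections"] < 1 or self.sampling["t_sec"] <= 0:
            raise ValueError("sampling needs n_sections >= 1 and t_sec > 0")
        if abs(sum(self.phantom["zone_fractions"]) - 1.0) > 1e-9:
            raise ValueError("zone fractions must sum to 1")
        for g in self.study["litters_per_group"]:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.estimators["krogh_K"] <= 0:
            raise ValueError("Krogh coefficient must be positive")

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {outputs, digests, seconds}

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": [str(p) for p in outputs],
            "digests": {str(p): file_digest(p) for p in outputs},
            "seconds": round(seconds, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def unchanged(self, stage: str) -> bool:
        rec = self.stages.get(stage)
        if not rec:
            return False
        try:
            return all(file_digest(p) == d for p, d in rec["digests"].items())
        except FileNotFoundError:
            return False


# ---------------------------------------------------------------------------
# per-placenta stereology

def analyze_placenta(cfg: PipelineConfig, phantom, fetal_weight_mg: float,
                     placental_weight_g: float,
                     rng: np.random.Generator) -> dict[str, float]:
    """Full stereological workup of one placenta phantom.

    Low power: Cavalieri total volume and zone volume fractions from SUR
    sections.  High power: fetal-capillary / maternal-blood-space volume
    and surface densities and orthogonal-intercept membrane thickness from
    a window on the midline section, referenced to the labyrinthine-zone
    volume.  Closes with diffusion capacities and efficiency ratios.
    """
    smp = cfg.sampling
    est = cfg.estimators
    stack = section_phantom(phantom, t_sec=smp["t_sec"],
                            n_select=smp["n_sections"], rng=rng,
                            pixel_size=smp["lowmag_pixel"])
    point_grid = GridSpec("point", smp["point_spacing"])
    per_label: dict[str, int] = {}
    per_section_tissue: list[int] = []
    for sec in stack:
        counts = overlay_point_grid(sec, point_grid, rng)
        tissue = 0
        for name, c in counts.items():
            if name in ("background", "outside"):
                continue
            per_label[name] = per_label.get(name, 0) + c
            tissue += c
        per_section_tissue.append(tissue)
    vol = cavalieri_volume(per_section_tissue, a_p=point_grid.a_p, d=stack.d)
    p_total = sum(per_label.values())
    zone_p = {z: 0 for z in ZONE_NAMES}
    for name, c in per_label.items():
        zone_p[ZONE_OF[name]] += c
    vv_zone = {z: volume_fraction(p, p_total) for z, p in zone_p.items()}
    v_zone = {z: absolute_volume(vv, vol.volume_um3)
              for z, vv in vv_zone.items()}
    vol.Vv.update(vv_zone)
    vol.absolute_um3.update(v_zone)

    # high-power window on the section closest to the midline (centroid)
    mid = 0.5 * (phantom.bbox_lo[0] + phantom.bbox_hi[0])
    z1 = phantom.z_cuts[0]
    c_ax = phantom.semi_axes[2]
    hw = smp["highmag_halfwidth"]
    raster = phantom.rasterize_section(
        mid, smp["highmag_pixel"], y_range=(-hw, hw),
        z_range=(-c_ax + 5.0, z1))
    field_img = SectionImage(labels=raster, pixel_size=smp["highmag_pixel"],
                             index=-1, plane_position=mid,
                             thickness=smp["t_sec"])
    lz_labels = ("labyrinth", "capillary", "blood_space")
    fine_grid = GridSpec("point", smp["fine_point_spacing"])
    fine_counts = overlay_point_grid(field_img, fine_grid, rng)
    p_lz = sum(fine_counts.get(n, 0) for n in lz_labels)
    if p_lz == 0:
        raise ValueError("no labyrinthine-zone points in high-power window")
    vv_fc = volume_fraction(fine_counts.get("capillary", 0), p_lz)
    vv_mbs = volume_fraction(fine_counts.get("blood_space", 0), p_lz)
    v_lz = v_zone["labyrinth"]
    v_fc = absolute_volume(vv_fc, v_lz)
    v_mbs = absolute_volume(vv_mbs, v_lz)

    cyc = GridSpec("cycloid", smp["cycloid_spacing"])
    fc_counts = overlay_cycloid_grid(field_img, cyc, structure="capillary",
                                     reference=lz_labels, rng=rng)
    mbs_counts = overlay_cycloid_grid(field_img, cyc, structure="blood_space",
                                      reference=lz_labels, rng=rng)
    s_fc = surface_area(fc_counts.sum_I, fc_counts.l_p, fc_counts.sum_P_ref,
                        v_lz)
    s_mbs = surface_area(mbs_counts.sum_I, mbs_counts.l_p,
                         mbs_counts.sum_P_ref, v_lz)

    intercepts = orthogonal_intercepts(field_img, line_spacing=smp["line_spacing"],
                                       rng=rng)
    tau = harmonic_mean_thickness(intercepts,
                                  correction=est["intercept_correction"])
    diff = diffusion_capacity(Quantity(s_fc.surface_um2, "um^2"),
                              Quantity(s_mbs.surface_um2, "um^2"),
                              Quantity(tau.tau_h_um, "um"),
                              K=est["krogh_K"])
    diff = specific_diffusion_capacity(diff, fetal_weight_mg)
    eff = placental_efficiency(fetal_weight_mg / 1e3, placental_weight_g,
                               Quantity(s_fc.surface_um2, "um^2"),
                               Quantity(s_mbs.surface_um2, "um^2"))
    out = {
        "volume_mm3": vol.volume_mm3,
        "tau_h_um": tau.tau_h_um,
        "n_intercepts": tau.n,
        "vv_fc": vv_fc,
        "vv_mbs": vv_mbs,
        "fc_volume_mm3": v_fc / 1e9,
        "mbs_volume_mm3": v_mbs / 1e9,
        "fc_surface_cm2": s_fc.surface_cm2,
        "mbs_surface_cm2": s_mbs.surface_cm2,
        "Dvm": diff.Dvm,
        "SDC": diff.SDC,
        "bw_pw": eff.bw_pw,
        "fw_per_fc_cm2": eff.fw_per_fc_cm2,
        "fw_per_mbs_cm2": eff.fw_per_mbs_cm2,
        "fw_per_total_cm2": eff.fw_per_total_cm2,
        "sum_P_cavalieri": vol.sum_P,
        "sum_I_fc": fc_counts.sum_I,
    }
    for z in ZONE_NAMES:
        out[f"vv_{z}"] = vv_zone[z]
        out[f"v_{z}_mm3"] = v_zone[z] / 1e9
    return out


# ---------------------------------------------------------------------------
# study simulation stages

def _stage_study(cfg: PipelineConfig, rng: np.random.Generator
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dam-level design table and fetus-level biometry table."""
    st = cfg.study
    spec = StudySynthSpec(
        litters_per_group=st["litters_per_group"],
        fetuses_per_litter=st["fetuses_per_litter"],
        group_means={"bw_g": {g: st["bw_mean_g"] for g in GROUPS}},
        sigma_litter={"bw_g": st["bw_sigma_litter"]},
        sigma_resid={"bw_g": st["bw_sigma_resid"]},
        seed=int(rng.integers(0, 2 ** 31)),
    )
    fetus = synth_study_table(spec)
    sex_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31)))
    fetus["sex"] = np.where(sex_rng.random(len(fetus)) < 0.5, "M", "F")
    # guarantee at least one male per litter for the sampling rule
    for dam, sub in fetus.groupby("dam_id"):
        if not (sub["sex"] == "M").any():
            fetus.loc[sub.index[0], "sex"] = "M"

    dams = []
    for dam, sub in fetus.groupby("dam_id", sort=False):
        g = sub["group"].iloc[0]
        hyp, mq = group_factors(g)
        scale = float(np.exp(rng.normal(0.0, st["litter_cv"])))
        males = sub[sub["sex"] == "M"]
        pick = males.iloc[int(rng.integers(0, len(males)))]
        dams.append({
            "dam_id": dam, "group": g, "hypoxia": hyp, "mitoq": mq,
            "volume_scale": st["volume_effect"][g] * scale,
            "capillary_scale": st["capillary_effect"][g] * scale,
            "channel_scale": st["channel_effect"][g] * scale,
            "fetus_id": pick["fetus_id"],
            "bw_g": float(pick["bw_g"]),
            "phantom_seed": int(rng.integers(0, 2 ** 31)),
            "analysis_seed": int(rng.integers(0, 2 ** 31)),
        })
    return pd.DataFrame(dams), fetus


def _stage_stereology(cfg: PipelineConfig, dams: pd.DataFrame) -> pd.DataFrame:
    ph_cfg = cfg.phantom
    rows = []
    for rec in dams.itertuples(index=False):
        lin = rec.volume_scale ** (1.0 / 3.0)
        n_cap = max(1, int(round(ph_cfg["n_capillaries"]
                                 * rec.capillary_scale / rec.volume_scale)))
        n_chan = max(1, int(round(ph_cfg["n_channels"]
                                  * rec.channel_scale / rec.volume_scale)))
        phantom, gt = make_placenta_phantom(
            zone_fractions=tuple(ph_cfg["zone_fractions"]),
            semi_axes=tuple(np.array(ph_cfg["semi_axes"]) * lin),
            n_capillaries=n_cap,
            capillary_radius=ph_cfg["capillary_radius"] * lin,
            n_channels=n_chan,
            channel_radius=ph_cfg["channel_radius"] * lin,
            tau_true=ph_cfg["tau_true"],
            seed=int(rec.phantom_seed),
        )
        pw_g = (gt.total_volume_um3 / 1e12) * cfg.study["pw_density_g_per_cm3"]
        rng = np.random.default_rng(int(rec.analysis_seed))
        res = analyze_placenta(cfg, phantom, fetal_weight_mg=rec.bw_g * 1e3,
                               placental_weight_g=pw_g, rng=rng)
        res.update({"dam_id": rec.dam_id, "group": rec.group,
                    "hypoxia": rec.hypoxia, "mitoq": rec.mitoq,
                    "pw_g": pw_g, "bw_g": rec.bw_g,
                    "true_volume_mm3": gt.total_volume_um3 / 1e9,
                    "true_fc_surface_cm2": gt.surfaces_um2["capillary"] / 1e8})
        rows.append(res)
    return pd.DataFrame(rows)


def _stage_densitometry(cfg: PipelineConfig, dams: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    den = cfg.densitometry
    n = len(dams)
    truth = np.array([
        den["expression_effect"][g] * np.exp(rng.normal(0.0, den["expression_cv"]))
        for g in dams["group"]])
    actin = den["actin_mean"] * np.exp(rng.normal(0.0, 0.05, size=n))
    target_abs = truth * actin

    fixture, _, _ = synth_blot_fixture(
        target_abs, np.array(den["exposure_gains"]),
        saturation_level=den["saturation"], noise_sd=den["noise_sd"],
        seed=int(rng.integers(0, 2 ** 31)))
    wide = fixture.pivot(index="lane", columns="exposure", values="intensity")
    sat = fixture.pivot(index="lane", columns="exposure", values="saturated")
    combined = combine_exposures(wide.to_numpy(), sat.to_numpy(),
                                 gains=np.array(den["exposure_gains"]))
    expr = normalize_expression(combined, actin, dams["group"],
                                control_group=cfg.stats["control_group"])
    expr.insert(0, "dam_id", dams["dam_id"].to_numpy())
    expr["hypoxia"] = dams["hypoxia"].to_numpy()
    expr["mitoq"] = dams["mitoq"].to_numpy()

    # immunostain OD per dam: uniform synthetic stain field read through the
    # step-tablet calibration
    tablet, pairs = make_step_tablet()
    cal = calibrate_od(pairs)
    grays = np.array([p[0] for p in pairs])
    ods = np.array([p[1] for p in pairs])
    od_rows = []
    for i, rec in enumerate(dams.itertuples(index=False)):
        od_true = den["od_mean"][rec.group] * float(
            np.exp(rng.normal(0.0, den["od_cv"])))
        od_true = float(np.clip(od_true, ods[0], ods[-1]))
        gray = float(np.interp(od_true, ods[::-1], grays[::-1]))
        img = np.full((96, 96), gray)
        img += rng.normal(0.0, 20.0, size=img.shape)
        img = np.clip(img, grays.min(), grays.max())
        mask = np.ones_like(img, dtype=bool)
        res = measure_region_od(img, cal, mask, n_fields=den["n_fields"],
                                field_px=16,
                                rng=np.random.default_rng(
                                    int(rng.integers(0, 2 ** 31))))
        od_rows.append({"dam_id": rec.dam_id, "group": rec.group,
                        "hypoxia": rec.hypoxia, "mitoq": rec.mitoq,
                        "region": "LZ", "mean_od": res.mean_od,
                        "sem_od": res.sem_od, "true_od": od_true})
    expr = expr.merge(pd.DataFrame(od_rows)[["dam_id", "mean_od", "true_od"]],
                      on="dam_id")
    return expr


STEREO_OUTCOMES = ["volume_mm3", "v_labyrinth_mm3", "v_junctional_mm3",
                   "v_decidua_mm3", "fc_volume_mm3", "mbs_volume_mm3",
                   "fc_surface_cm2", "mbs_surface_cm2", "tau_h_um",
                   "Dvm", "SDC", "bw_pw", "fw_per_fc_cm2", "fw_per_mbs_cm2"]


def _stage_stats(cfg: PipelineConfig, stereo: pd.DataFrame,
                 expr: pd.DataFrame, fetus: pd.DataFrame) -> dict:
    fits = {}
    for outcome in STEREO_OUTCOMES:
        fit = glm_two_factor(stereo, outcome)
        fits[outcome] = _fit_to_dict(fit)
    for outcome in ("relative", "mean_od"):
        fits[outcome] = _fit_to_dict(glm_two_factor(expr, outcome))
    biom = fetus[fetus["sex"] == "M"] if cfg.study["male_only"] else fetus
    fits["bw_g"] = _fit_to_dict(lmm_litter(biom, "bw_g"))
    return fits


def _fit_to_dict(fit) -> dict:
    return {
        "method": fit.method,
        "outcome": fit.outcome,
        "coefficients": fit.coefficients,
        "se": fit.se,
        "sigma2_resid": fit.sigma2_resid,
        "sigma2_group": fit.sigma2_group,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "effects": {k: {"estimate": e.estimate, "se": e.se, "F": e.F,
                        "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                        "significant": e.significant}
                    for k, e in fit.effects.items()},
    }


def _stage_report(stereo: pd.DataFrame, expr: pd.DataFrame,
                  fits: dict) -> pd.DataFrame:
    rows = []
    for outcome in STEREO_OUTCOMES:
        for g, sub in stereo.groupby("group"):
            vals = sub[outcome]
            rows.append({
                "outcome": outcome, "group": g, "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)),
                "n": len(vals),
                "p_hypoxia": fits[outcome]["effects"]["hypoxia"]["p"],
                "p_mitoq": fits[outcome]["effects"]["mitoq"]["p"],
            })
    for g, sub in expr.groupby("group"):
        rows.append({"outcome": "relative_expression", "group": g,
                     "mean": sub["relative"].mean(),
                     "sem": sub["relative"].std(ddof=1) / np.sqrt(len(sub)),
                     "n": len(sub),
                     "p_hypoxia": fits["relative"]["effects"]["hypoxia"]["p"],
                     "p_mitoq": fits["relative"]["effects"]["mitoq"]["p"]})
    return pd.DataFrame(rows)


def simulate_study(cfg: PipelineConfig, seed: int) -> dict:
    """One in-memory replicate of the four-group study (no file output).

    Returns the stats-stage fit dictionary keyed by outcome.
    """
    d = cfg.to_dict()
    d["seed"] = seed
    cfg = PipelineConfig.from_dict(d)
    rng = np.random.default_rng(cfg.seed)
    seeds = {s: int(rng.integers(0, 2 ** 31))
             for s in ("study", "stereology", "densitometry")}
    dams, fetus = _stage_study(cfg, np.random.default_rng(seeds["study"]))
    stereo = _stage_stereology(cfg, dams)
    expr = _stage_densitometry(cfg, dams,
                               np.random.default_rng(seeds["densitometry"]))
    return _stage_stats(cfg, stereo, expr, fetus)


def estimate_power(cfg: PipelineConfig, outcome: str, effect: str,
                   n_replicates: int, seed: int) -> float:
    """Empirical power: fraction of replicate studies whose GLM flags
    ``effect`` on ``outcome`` at the configured significance level."""
    hits = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        fits = simulate_study(cfg, int(rng.integers(0, 2 ** 31)))
        hits += bool(fits[outcome]["effects"][effect]["significant"])
    return hits / n_replicates


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 resume: bool = False) -> RunManifest:
    """Execute all stages, writing a results tree and manifest under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        manifest = RunManifest(config_hash=prev["config_hash"],
                               seed=prev["seed"], version=prev["version"],
                               stages=prev["stages"])
        if manifest.config_hash != cfg.hash:
            manifest = RunManifest(config_hash=cfg.hash, seed=cfg.seed,
                                   version=__version__)
    else:
        manifest = RunManifest(config_hash=cfg.hash, seed=cfg.seed,
                               version=__version__)
    rng = np.random.default_rng(cfg.seed)
    # draw stage seeds up front so resume keeps downstream streams stable
    stage_seeds = {s: int(rng.integers(0, 2 ** 31))
                   for s in ("study", "stereology", "densitometry")}

    def run_stage(name: str, fn, outputs: list[Path]):
        if resume and manifest.unchanged(name):
            log.info("stage %s unchanged; skipping", name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, cfg.hash, str(e)) from e
        manifest.record(name, outputs, time.perf_counter() - t0)
        write_json({"config_hash": manifest.config_hash,
                    "seed": manifest.seed, "version": manifest.version,
                    "stages": manifest.stages}, manifest_path)
        log.info("stage %s done in %.2fs", name,
                 manifest.stages[name]["seconds"])

    study_csv = out / "study_table.csv"
    fetus_csv = out / "fetus_table.csv"
    config_yaml = out / "config.yaml"

    def do_study():
        config_yaml.write_text(yaml.safe_dump(cfg.to_dict()))
        dams, fetus = _stage_study(
            cfg, np.random.default_rng(stage_seeds["study"]))
        dams.to_csv(study_csv, index=False)
        fetus.to_csv(fetus_csv, index=False)

    run_stage("study", do_study, [study_csv, fetus_csv, config_yaml])

    stereo_csv = out / "stereology.csv"

    def do_stereo():
        dams = pd.read_csv(study_csv)
        _stage_stereology(cfg, dams).to_csv(stereo_csv, index=False)

    run_stage("stereology", do_stereo, [stereo_csv])

    expr_csv = out / "expression.csv"

    def do_densito():
        dams = pd.read_csv(study_csv)
        _stage_densitometry(
            cfg, dams,
            np.random.default_rng(stage_seeds["densitometry"])
        ).to_csv(expr_csv, index=False)

    run_stage("densitometry", do_densito, [expr_csv])

    stats_json = out / "stats.json"

    def do_stats():
        stereo = pd.read_csv(stereo_csv)
        expr = pd.read_csv(expr_csv)
        fetus = pd.read_csv(fetus_csv)
        fits = _stage_stats(cfg, stereo, expr, fetus)
        write_json({"config_hash": cfg.hash, "fits": fits}, stats_json)

    run_stage("stats", do_stats, [stats_json])

    report_csv = out / "report.csv"

    def do_report():
        stereo = pd.read_csv(stereo_csv)
        expr = pd.read_csv(expr_csv)
        fits = json.loads(stats_json.read_text())["fits"]
        _stage_report(stereo, expr, fits).to_csv(report_csv, index=False)

    run_stage("report", do_report, [report_csv])
    return manifest
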