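"""End-to-end pipeline: simulate/load → fit → bootstrap → integrate → dose.

``run_pipeline`` executes the full chain and writes one file per stage plus a
provenance manifest into the output directory. Reruns with an identical
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .cumulated_activity import CumulatedActivity, ResamplingScheme, bootstrap_tiac_ci
from .dose_engine import (
    TOTAL_BODY,
    DoseReport,
    build_dose_table,
    cumulated_activity_absolute,
    extrapolate_human_tiac,
)
from .errors import ValidationError
from .growth_metrics import fit_exponential_growth, summarize_groups
from .io import (
    read_biodistribution_csv,
    read_caliper_csv,
    read_organ_map,
    read_svalue_table,
    write_biodistribution_csv,
    write_growth_table,
    write_tiac_table,
)
from .pk_models import FitOptions, OrganClass, assign_model_family
from .synthetic_data import SimulationConfig, samples_to_series, simulate_biodistribution

__all__ = ["PipelineConfig", "run_pipeline", "packaged_data_path"]


def packaged_data_path(name: str) -> Path:
    """Path to a data file shipped with the package (fixtures, templates)."""
    return Path(resources.files("tracedose.data") / name)


#: Organs whose time-activity family differs from the bi-exponential default.
DEFAULT_ORGAN_CLASSES = {"tumor": "tumor", "eyes": "eye"}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    biodistribution_csv: str | None = None  # None -> simulate
    caliper_csv: str | None = None
    svalues_mouse: str = str(packaged_data_path("svalues_mouse_synthetic.tsv"))
    masses_mouse: str = str(packaged_data_path("masses_mouse_synthetic.tsv"))
    svalues_human: str = str(packaged_data_path("svalues_human_synthetic.tsv"))
    masses_human: str = str(packaged_data_path("masses_human_synthetic.tsv"))
    organ_map: str = str(packaged_data_path("organ_map_mouse_human.yaml"))
    organ_classes: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_CLASSES))
    therapy_activity_mbq: float = 18.5  # murine therapeutic injection
    human_activity_gbq: float = 3.7  # standard clinical iodine-TRT activity
    n_resamples: int = 153
    scheme: str = "combined"
    robust: bool = True
    half_life_h: float = 192.6
    dose_mode: str = "self"
    strategy: str = "relative_mass"
    seed: int = 0

    def __post_init__(self):
        if self.therapy_activity_mbq <= 0 or self.human_activity_gbq <= 0:
            raise ValidationError("injected activities must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fit_options(cfg: PipelineConfig) -> FitOptions:
    return FitOptions(robust=cfg.robust, half_life_h=cfg.half_life_h)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write per-stage outputs under ``outdir``.

    Returns a summary dict with the tiac results, mouse and human dose
    reports, and (when caliper data are configured) growth fits.
    """
    cfg = config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    opts = _fit_options(cfg)

    # --- stage: input biodistribution ------------------------------------
    if cfg.biodistribution_csv is None:
        samples, _truth = simulate_biodistribution(
            SimulationConfig(half_life_h=cfg.half_life_h, seed=cfg.seed)
        )
        write_biodistribution_csv(samples, out / "biodistribution.csv")
    else:
        samples = read_biodistribution_csv(cfg.biodistribution_csv)
    series = samples_to_series(samples, half_life_h=cfg.half_life_h)

    # --- stage: fit + bootstrap + integrate -------------------------------
    tiac_results: list[CumulatedActivity] = []
    for organ in sorted(series):
        organ_class = cfg.organ_classes.get(organ, "other")
        family = assign_model_family(OrganClass(organ_class))
        tiac_results.append(
            bootstrap_tiac_ci(
                series[organ],
                family,
                n_resamples=cfg.n_resamples,
                scheme=ResamplingScheme(cfg.scheme),
                seed=cfg.seed,
                options=opts,
            )
        )
    write_tiac_table(tiac_results, out / "tiac.csv")

    # --- stage: mouse dose -------------------------------------------------
    mouse_table = read_svalue_table(cfg.svalues_mouse, cfg.masses_mouse, "mouse")
    tiac_per_g = {r.organ: r.tiac for r in tiac_results}
    cumulated_mouse = {
        organ: cumulated_activity_absolute(
            tiac, mouse_table.mass(organ), cfg.therapy_activity_mbq
        )
        for organ, tiac in tiac_per_g.items()
    }
    mouse_report = build_dose_table(
        cumulated_mouse,
        mouse_table,
        cfg.therapy_activity_mbq,
        species="mouse",
        mode=cfg.dose_mode,
        seed=cfg.seed,
    )
    mouse_report.provenance["config_hash"] = cfg.config_hash()
    mouse_report.provenance["version"] = __version__
    mouse_report.to_csv(out / "dose_mouse.csv")
    mouse_report.to_json(out / "dose_mouse.json")

    # --- stage: human extrapolation + dose ---------------------------------
    human_table = read_svalue_table(cfg.svalues_human, cfg.masses_human, "human")
    organ_map = read_organ_map(cfg.organ_map)
    mapped = {o: t for o, t in tiac_per_g.items() if o in organ_map}
    human_tiac = extrapolate_human_tiac(
        mapped, mouse_table, human_table, strategy=cfg.strategy, organ_map=organ_map
    )
    inj_human_mbq = cfg.human_activity_gbq * 1000.0
    cumulated_human = {o: t * inj_human_mbq for o, t in human_tiac.items()}
    human_report = build_dose_table(
        cumulated_human,
        human_table,
        cfg.human_activity_gbq,
        species="human",
        mode=cfg.dose_mode,
        activity_unit="GBq",
        seed=cfg.seed,
    )
    human_report.provenance["config_hash"] = cfg.config_hash()
    human_report.provenance["version"] = __version__
    human_report.provenance["strategy"] = cfg.strategy
    human_report.to_csv(out / "dose_human.csv")
    human_report.to_json(out / "dose_human.json")

    # --- stage: growth -------------------------------------------------------
    growth_fits = None
    if cfg.caliper_csv is not None:
        records = read_caliper_csv(cfg.caliper_csv)
        growth_fits = [fit_exponential_growth(r) for r in records]
        write_growth_table(growth_fits, out / "growth.csv")
        summarize_groups(growth_fits).to_csv(
            out / "growth_groups.csv", index=False, float_format="%.10g"
        )

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": ["biodistribution", "tiac", "dose_mouse", "dose_human"]
        + (["growth"] if growth_fits is not None else []),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "tiac": tiac_results,
        "dose_mouse": mouse_report,
        "dose_human": human_report,
        "growth": growth_fits,
        "manifest": manifest,
    }
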