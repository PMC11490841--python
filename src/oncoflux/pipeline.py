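"""End-to-end orchestration with a provenance manifest.

A :class:`RunConfig` names the input files and stage toggles; `run_pipeline`
executes the enabled stages in dependency order (ingest → normalise →
summarise → ATP / MID / statistics), writes TSV outputs, and records a
manifest with the config echo, input digests and per-stage status.  A stage
failure marks dependent stages skipped and the run as errored.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .flux import (
    BioenergeticCoefficients,
    atp_fluxes,
    group_means,
    normalize_plate,
    respiratory_params,
    summarize_phases,
)
from .io import read_flux_plate, read_od_table, read_protocol, read_table
from .isotopes import DEFAULT_ISOTOPES, default_fragment_registry, load_fragment_registry
from .mids import LabellingMeasurement, build_correction_matrix, correct_mid, ratio_to_mean, total_enrichment
from .stats import differential_proteome

logger = logging.getLogger("oncoflux")

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "flux_trace", "od", "protocol", "intensities", "fragment_registry",
    "proteome", "sample_sheet", "groups", "stages", "coefficients",
    "aggregators", "strict", "seed",
}


@dataclass
class RunConfig:
    """Validated run configuration; serialised verbatim into the manifest."""

    flux_trace: str | None = None
    od: str | None = None
    protocol: str | None = None
    intensities: str | None = None
    fragment_registry: str | None = None
    proteome: str | None = None
    sample_sheet: str | None = None
    groups: tuple[str, str] | None = None  # contrast for the proteome stage
    stages: tuple[str, ...] = ("flux", "mid", "mid_heatmap", "proteome")
    coefficients: dict = field(default_factory=dict)
    aggregators: dict = field(default_factory=dict)
    strict: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, strict: bool | None = None) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        is_strict = raw.get("strict", False) if strict is None else strict
        if unknown and is_strict:
            raise ValueError(f"unknown config keys (strict mode): {sorted(unknown)}")
        raw = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
        if "groups" in raw and raw["groups"] is not None:
            raw["groups"] = tuple(raw["groups"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        if strict is not None:
            cfg.strict = strict
        if cfg.strict and cfg.stages and "flux" in cfg.stages:
            if "buffering_power" not in cfg.coefficients:
                raise ValueError(
                    "strict mode requires an explicit buffering_power coefficient"
                )
        return cfg

    def bioenergetic_coefficients(self) -> BioenergeticCoefficients:
        return BioenergeticCoefficients(**self.coefficients)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


_STAGE_DEPS = {"mid_heatmap": ("mid",)}


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run all enabled stages, write outputs + manifest, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "oncoflux",
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for key in ("flux_trace", "od", "protocol", "intensities", "proteome", "sample_sheet"):
        path = getattr(cfg, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _digest(path)}

    state: dict = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        manifest["outputs"].append({"file": name, "sha256": _digest(path)})

    def _run_stage(name, fn):
        for dep in _STAGE_DEPS.get(name, ()):
            if manifest["stages"].get(dep, {}).get("status") != "ok":
                manifest["stages"][name] = {"status": "skipped", "reason": f"dependency {dep!r} not ok"}
                return
        try:
            warnings = fn()
            manifest["stages"][name] = {"status": "ok", "warnings": warnings or []}
        except Exception as exc:  # recorded, not raised: manifest carries the failure
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "error", "message": str(exc)}

    def _stage_flux():
        plate = read_flux_plate(cfg.flux_trace)
        od = read_od_table(cfg.od)
        protocol = read_protocol(cfg.protocol)
        norm = normalize_plate(plate, od)
        ps = summarize_phases(norm, protocol, cfg.aggregators or None)
        rp = respiratory_params(ps)
        coef = cfg.bioenergetic_coefficients()
        atp = atp_fluxes(ps, rp, coef)
        per_well = pd.concat([ps.table, rp, atp], axis=1)
        _write("flux_per_well.tsv", per_well)
        _write("flux_per_group.tsv", group_means(per_well, ps.groups))
        manifest["flux_meta"] = {"aggregators": dict(ps.aggregators), "coefficients": coef.to_dict()}
        state["flux"] = per_well
        n_flagged = int(rp["flagged"].sum())
        return [f"{n_flagged} well(s) with clamped rates"] if n_flagged else []

    def _stage_mid():
        table = read_table(cfg.intensities, "intensities")
        registry = (
            load_fragment_registry(cfg.fragment_registry)
            if cfg.fragment_registry
            else default_fragment_registry()
        )
        warnings: list[str] = []
        mid_rows, enrich_rows = [], []
        abundances: dict[str, dict[str, float]] = {}
        for (metabolite, sample), grp in table.groupby(["metabolite", "sample"]):
            if metabolite not in registry:
                raise KeyError(f"metabolite {metabolite!r} not in fragment registry")
            grp = grp.sort_values("mass_shift")
            meas = LabellingMeasurement(
                metabolite=metabolite,
                intensities=grp["intensity"].to_numpy(),
                internal_standard=float(grp["internal_standard"].iloc[0])
                if "internal_standard" in grp
                else float("nan"),
                cell_count=float(grp["cell_count"].iloc[0]) if "cell_count" in grp else None,
            )
            cm = build_correction_matrix(registry[metabolite], DEFAULT_ISOTOPES)
            mid = correct_mid(meas, cm)
            warnings.extend(f"{metabolite}/{sample}: {w}" for w in mid.warnings)
            for i, frac in enumerate(mid.fractions):
                mid_rows.append(
                    {"metabolite": metabolite, "sample": sample, "isotopologue": i, "fraction": frac}
                )
            enrich_rows.append(
                {
                    "metabolite": metabolite,
                    "sample": sample,
                    "enrichment": total_enrichment(mid),
                    "residual": mid.residual,
                    "condition_number": mid.condition_number,
                }
            )
            abundances.setdefault(metabolite, {})[sample] = float(grp["intensity"].sum())
        _write("mids.tsv", pd.DataFrame(mid_rows).set_index(["metabolite", "sample"]))
        _write("enrichment.tsv", pd.DataFrame(enrich_rows).set_index(["metabolite", "sample"]))
        state["mid_abundances"] = pd.DataFrame(abundances).T
        return warnings

    def _stage_mid_heatmap():
        ab = state["mid_abundances"]
        _write("log2_ratio_to_mean.tsv", ratio_to_mean(ab))
        return []

    def _stage_proteome():
        tbl = read_table(cfg.proteome, "proteome")
        sheet = read_table(cfg.sample_sheet, "sample_sheet")
        groups = sheet.set_index("sample")["group"]
        g1, g2 = cfg.groups or tuple(pd.unique(groups))[:2]
        res = differential_proteome(tbl, groups, g1, g2)
        _write("differential_proteome.tsv", res)
        return [f"{int(res['significant'].sum())} significant protein(s)"]

    stage_fns = {
        "flux": _stage_flux,
        "mid": _stage_mid,
        "mid_heatmap": _stage_mid_heatmap,
        "proteome": _stage_proteome,
    }
    inputs_needed = {
        "flux": ("flux_trace", "od", "protocol"),
        "mid": ("intensities",),
        "mid_heatmap": (),
        "proteome": ("proteome", "sample_sheet"),
    }
    for name in cfg.stages:
        if name not in stage_fns:
            raise ValueError(f"unknown stage {name!r}")
        if any(getattr(cfg, k) is None for k in inputs_needed[name]):
            manifest["stages"][name] = {"status": "skipped", "reason": "inputs not configured"}
            continue
        _run_stage(name, stage_fns[name])

    manifest["ok"] = all(
        s.get("status") != "error" for s in manifest["stages"].values() if isinstance(s, dict)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
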