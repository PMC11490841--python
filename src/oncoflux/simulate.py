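"""Synthetic instrument outputs with known ground truth.

Every pipeline stage is testable without deposited data: simulated flux
plates share the analysis code's phase/protocol structure, simulated
labelling intensities are produced by the same correction-matrix forward
model the corrector inverts, and simulated proteome tables carry explicit
spiked effects.  Each simulator returns a :class:`SyntheticTruth` recording
the generating parameters and seed; regeneration from (parameters, seed)
is bit-identical.

Noise models — additive Gaussian on flux rates, multiplicative log-normal
on ion intensities and protein abundances — are standard instrument-noise
shapes, with magnitudes exposed as parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flux import FluxPlate, InjectionProtocol, NormalizationTable
from .isotopes import DEFAULT_ISOTOPES, FragmentSpec, IsotopeTable
from .mids import build_correction_matrix

__all__ = [
    "SyntheticTruth",
    "FluxDesign",
    "simulate_flux_plate",
    "simulate_labelling",
    "simulate_omics",
]

PHASE_ORDER = ("basal", "oligomycin", "fccp", "antimycin_rotenone", "monensin")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters and seed for one simulated dataset."""

    kind: str
    seed: int
    params: dict

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not serialisable: {type(o)}")

        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params},
            default=_default,
            sort_keys=True,
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


@dataclass(frozen=True)
class FluxDesign:
    """Per-group normalised plateau rates for each stress-test phase.

    ``ocr``/``ecar`` map phase name → plateau in per-OD-unit rate; raw
    well-level traces are these plateaus multiplied by the well's
    cell-number factor and OD base, so OD595 normalisation recovers them.
    """

    ocr: Mapping[str, float]
    ecar: Mapping[str, float]

    def __post_init__(self) -> None:
        for signal in (self.ocr, self.ecar):
            for phase, v in signal.items():
                if phase not in PHASE_ORDER:
                    raise ValueError(f"unknown phase {phase!r}")
                if v < 0:
                    raise ValueError(f"negative plateau for {phase!r}: {v}")


# a typical adenoma-to-carcinoma style contrast: a glycolytic group with
# high ECAR/low spare capacity vs an oxidative group with high FCCP response
DEFAULT_FLUX_DESIGN: dict[str, FluxDesign] = {
    "glycolytic": FluxDesign(
        ocr={"basal": 80.0, "oligomycin": 30.0, "fccp": 110.0,
             "antimycin_rotenone": 15.0, "monensin": 25.0},
        ecar={"basal": 45.0, "oligomycin": 60.0, "fccp": 55.0,
              "antimycin_rotenone": 50.0, "monensin": 80.0},
    ),
    "oxidative": FluxDesign(
        ocr={"basal": 120.0, "oligomycin": 40.0, "fccp": 260.0,
             "antimycin_rotenone": 20.0, "monensin": 35.0},
        ecar={"basal": 20.0, "oligomycin": 35.0, "fccp": 30.0,
              "antimycin_rotenone": 25.0, "monensin": 45.0},
    ),
}


def simulate_flux_plate(
    design: Mapping[str, FluxDesign] | None = None,
    wells_per_group: int = 12,
    noise_sd: float = 3.0,
    cell_spread: float = 0.1,
    od_base: float = 0.5,
    od_noise_sd: float = 0.01,
    cycles_per_phase: int = 3,
    cycle_minutes: float = 6.5,
    seed: int = 0,
) -> tuple[FluxPlate, NormalizationTable, InjectionProtocol, SyntheticTruth]:
    """Simulate a raw stress-test plate plus its OD595 table and protocol.

    Per well: raw rate = plateau × (od_base × cell factor) + Gaussian noise
    with sd ``noise_sd`` (in the same raw rate units); OD595 = od_base ×
    the same cell factor × (1 + small Gaussian noise).  Cell factors are
    log-normal with sd ``cell_spread`` so normalisation tests exercise a
    real spread.
    """
    if design is None:
        design = DEFAULT_FLUX_DESIGN
    if not design:
        raise ValueError("need at least one group")
    if cycles_per_phase < 1:
        raise ValueError("each phase needs >=1 cycle")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n_phases = len(PHASE_ORDER)
    n_cycles = n_phases * cycles_per_phase
    phase_of_cycle = np.repeat(np.arange(n_phases), cycles_per_phase)

    rows, ocr_rows, ecar_rows, od = [], [], [], {}
    for group, gdesign in design.items():
        ocr_plateaus = np.array([gdesign.ocr[p] for p in PHASE_ORDER])
        ecar_plateaus = np.array([gdesign.ecar[p] for p in PHASE_ORDER])
        for w in range(wells_per_group):
            well_id = f"{group}_{w:02d}"
            f = float(np.exp(rng.normal(0.0, cell_spread)))
            scale = od_base * f
            ocr_rows.append(
                ocr_plateaus[phase_of_cycle] * scale + rng.normal(0.0, noise_sd, n_cycles)
            )
            ecar_rows.append(
                ecar_plateaus[phase_of_cycle] * scale + rng.normal(0.0, noise_sd, n_cycles)
            )
            od[well_id] = scale * (1.0 + rng.normal(0.0, od_noise_sd))
            rows.append({"well_id": well_id, "group": group, "condition": group,
                         "cell_factor": f})

    wells = pd.DataFrame(rows)
    plate = FluxPlate(
        wells=wells[["well_id", "group", "condition"]],
        cycles=np.arange(1, n_cycles + 1) * cycle_minutes,
        ocr=np.vstack(ocr_rows),
        ecar=np.vstack(ecar_rows),
        normalised=False,
    )
    protocol = InjectionProtocol(
        events=tuple(
            (name, (i + 1) * cycles_per_phase) for i, name in enumerate(PHASE_ORDER[1:])
        )
    )
    truth = SyntheticTruth(
        kind="flux_plate",
        seed=seed,
        params={
            "design": {
                g: {"ocr": dict(d.ocr), "ecar": dict(d.ecar)} for g, d in design.items()
            },
            "wells_per_group": wells_per_group,
            "noise_sd": noise_sd,
            "cell_spread": cell_spread,
            "od_base": od_base,
            "od_noise_sd": od_noise_sd,
            "cycles_per_phase": cycles_per_phase,
            "cell_factors": {r["well_id"]: r["cell_factor"] for r in rows},
        },
    )
    return plate, NormalizationTable(od595=od), protocol, truth


# glutamine-anaplerosis-like default truth MIDs (m+4/m+5 patterns on
# five-carbon metabolites, m+2 TCA entry on others)
DEFAULT_TRUTH_MIDS: dict[str, list[float]] = {
    "glutamine": [0.25, 0.02, 0.02, 0.02, 0.04, 0.65],
    "glutamate": [0.40, 0.03, 0.04, 0.05, 0.08, 0.40],
    "alpha-ketoglutarate": [0.45, 0.03, 0.05, 0.06, 0.09, 0.32],
    "succinate": [0.55, 0.05, 0.08, 0.07, 0.25],
    "fumarate": [0.58, 0.05, 0.08, 0.07, 0.22],
    "malate": [0.56, 0.05, 0.09, 0.08, 0.22],
    "aspartate": [0.60, 0.05, 0.08, 0.07, 0.20],
    "citrate": [0.55, 0.04, 0.08, 0.07, 0.12, 0.06, 0.08],
}


def simulate_labelling(
    truth_mids: Mapping[str, Sequence[float]] | None = None,
    registry: Mapping[str, FragmentSpec] | None = None,
    abundances: Mapping[str, float] | None = None,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    internal_standard: float = 1e5,
    cell_count: float = 1e6,
    iso: IsotopeTable = DEFAULT_ISOTOPES,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate raw SIM intensity tables from ground-truth MIDs.

    Measured intensities are ``abundance × (correction_matrix @ truth_mid)``
    perturbed by multiplicative log-normal noise with log-sd ``noise_sd`` —
    the exact forward model :func:`oncoflux.mids.correct_mid` inverts.

    Returns a long table (metabolite, replicate, mass_shift, intensity,
    internal_standard, cell_count) and the truth record.
    """
    if registry is None:
        from .isotopes import default_fragment_registry

        registry = default_fragment_registry()
    if truth_mids is None:
        truth_mids = DEFAULT_TRUTH_MIDS
    if abundances is None:
        abundances = {m: 1e6 for m in truth_mids}

    rng = np.random.default_rng(seed)
    records = []
    for metabolite, x in truth_mids.items():
        if metabolite not in registry:
            raise KeyError(f"metabolite {metabolite!r} not in fragment registry")
        frag = registry[metabolite]
        x = np.asarray(x, dtype=float)
        if x.size != frag.n_tracer_carbons + 1:
            raise ValueError(
                f"{metabolite}: truth MID length {x.size} != "
                f"n_tracer_carbons+1 ({frag.n_tracer_carbons + 1})"
            )
        x = x / x.sum()
        cm = build_correction_matrix(frag, iso)
        clean = abundances[metabolite] * (cm.matrix @ x)
        for rep in range(n_replicates):
            noisy = clean * np.exp(rng.normal(0.0, noise_sd, clean.size))
            is_noisy = internal_standard * float(np.exp(rng.normal(0.0, noise_sd)))
            for shift, intensity in enumerate(noisy):
                records.append(
                    {
                        "metabolite": metabolite,
                        "replicate": rep,
                        "mass_shift": shift,
                        "intensity": intensity,
                        "internal_standard": is_noisy,
                        "cell_count": cell_count,
                    }
                )
    table = pd.DataFrame.from_records(records)
    truth = SyntheticTruth(
        kind="labelling",
        seed=seed,
        params={
            "truth_mids": {m: list(np.asarray(v, float) / np.sum(v)) for m, v in truth_mids.items()},
            "abundances": dict(abundances),
            "noise_sd": noise_sd,
            "n_replicates": n_replicates,
            "internal_standard": internal_standard,
            "cell_count": cell_count,
            "tracer_purity": iso.tracer_purity,
        },
    )
    return table, truth


def simulate_omics(
    n_proteins: int = 2000,
    samples_per_group: tuple[int, int] = (3, 3),
    effects: Sequence[tuple[int, float]] = (),
    log2_noise_sd: float = 0.25,
    baseline_log2_mean: float = 20.0,
    baseline_log2_sd: float = 2.0,
    growth_rates: Mapping[str, float] | None = None,
    growth_hours: int = 96,
    growth_interval_h: int = 4,
    growth_noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Simulate a spiked proteome table plus confluence growth curves.

    Protein abundances are log-normal: per-protein baseline log₂ level ~
    N(baseline_log2_mean, baseline_log2_sd), per-sample replicate noise
    N(0, log2_noise_sd) on the log₂ scale, and each spiked effect
    ``(protein_index, delta_log2)`` added to group B samples.  Growth
    curves are logistic confluence per condition with observation noise.

    Returns (abundance frame, sample→group series, growth frame, truth).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    for idx, _ in effects:
        if not 0 <= idx < n_proteins:
            raise ValueError(f"effect index {idx} out of range [0, {n_proteins})")
    if growth_rates is None:
        growth_rates = {"control": 0.08, "treated": 0.04}

    rng = np.random.default_rng(seed)
    n_a, n_b = samples_per_group
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, n_proteins)
    log2 = base[:, None] + rng.normal(0.0, log2_noise_sd, (n_proteins, n_a + n_b))
    for idx, delta in effects:
        log2[idx, n_a:] += delta
    samples = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n_b)]
    abundance = pd.DataFrame(
        np.exp2(log2),
        index=[f"P{i:05d}" for i in range(n_proteins)],
        columns=samples,
    )
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="group")

    times = np.arange(0, growth_hours + 1, growth_interval_h, dtype=float)
    growth_records = []
    for condition, rate in growth_rates.items():
        # logistic rise from 10% confluence toward 95% capacity
        conf = 95.0 / (1.0 + (95.0 / 10.0 - 1.0) * np.exp(-rate * times))
        noisy = np.clip(conf + rng.normal(0.0, growth_noise_sd, conf.size), 0.1, 100.0)
        for t, c in zip(times, noisy):
            growth_records.append({"condition": condition, "time_h": t, "confluence": c})
    growth = pd.DataFrame.from_records(growth_records)

    truth = SyntheticTruth(
        kind="omics",
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "samples_per_group": list(samples_per_group),
            "effects": [[int(i), float(d)] for i, d in effects],
            "log2_noise_sd": log2_noise_sd,
            "growth_rates": dict(growth_rates),
            "growth_noise_sd": growth_noise_sd,
        },
    )
    return abundance, groups, growth, truth
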