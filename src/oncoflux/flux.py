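"""Extracellular-flux bioenergetics: plate traces → ATP production rates.

Implements the mitochondrial stress-test arithmetic for plate-format
oxygen-consumption (OCR, pmol O₂/min) and extracellular-acidification
(ECAR, mpH/min) traces:

* crystal-violet (OD595) normalisation to cell number,
* per-phase trace aggregation around the injection sequence
  (oligomycin → FCCP → antimycin A + rotenone → monensin),
* respiratory parameters (mitochondrial, coupled and leak respiration,
  maximal and spare respiratory capacity), and
* the decomposition of ATP production into glycolytic and oxidative
  rates (J_ATP-glycolysis, J_ATP-OxPhos) with the glycolytic index.

The ATP accounting follows the standard extracellular-flux framework:
total proton production is ECAR divided by the medium buffering power; the
respiratory (CO₂/bicarbonate) share is subtracted using the medium pH and
carbonic-acid pK₁; the glycolytic remainder converts to ATP at one ATP per
lactate, plus substrate-level and oxidative terms proportional to oxygen
consumption with P/O coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluxPlate",
    "InjectionProtocol",
    "NormalizationTable",
    "PhaseSummary",
    "BioenergeticCoefficients",
    "DEFAULT_AGGREGATORS",
    "normalize_plate",
    "summarize_phases",
    "respiratory_params",
    "atp_fluxes",
    "nutrient_stress_ratio",
    "group_compare",
    "group_means",
    "star_code",
]

KNOWN_INJECTIONS = ("oligomycin", "fccp", "antimycin_rotenone", "monensin")


class ProtocolError(ValueError):
    """Raised for malformed injection protocols."""


@dataclass(frozen=True)
class FluxPlate:
    """Well × measurement-cycle OCR/ECAR traces.

    ``ocr`` and ``ecar`` have shape (n_wells, n_cycles); ``cycles`` holds
    measurement times in minutes.  All wells share the cycle grid.
    """

    wells: pd.DataFrame  # columns: well_id, group, condition
    cycles: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        n_wells = len(self.wells)
        n_cycles = len(self.cycles)
        for name in ("ocr", "ecar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n_wells, n_cycles):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n_wells, n_cycles)}"
                )
            if np.isnan(arr).any():
                raise ValueError(f"{name} contains NaN (missing cycles are an ingestion error)")
            object.__setattr__(self, name, arr)
        if not {"well_id", "group"}.issubset(self.wells.columns):
            raise ValueError("wells table needs well_id and group columns")
        if self.wells["well_id"].duplicated().any():
            raise ValueError("duplicate well_id in plate")

    @property
    def well_ids(self) -> list[str]:
        return list(self.wells["well_id"])

    @property
    def groups(self) -> pd.Series:
        return self.wells.set_index("well_id")["group"]


@dataclass(frozen=True)
class InjectionProtocol:
    """Ordered injection events defining half-open phase windows.

    Each event is ``(name, first_cycle_index)``; the basal phase covers all
    cycles before the first event, and each injection phase runs from its
    first cycle to the next event's first cycle (or the end of the trace).
    """

    events: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        idx = [c for _, c in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ProtocolError("injection first_cycle indices must be strictly increasing")
        for name, c in self.events:
            if name not in KNOWN_INJECTIONS:
                raise ProtocolError(f"unknown injection {name!r}")
            if c < 1:
                raise ProtocolError(f"{name}: first_cycle_index must leave >=1 basal cycle")

    def phases(self, n_cycles: int) -> dict[str, slice]:
        """Phase name → cycle slice; every cycle belongs to exactly one phase."""
        bounds = [c for _, c in self.events] + [n_cycles]
        out = {"basal": slice(0, bounds[0])}
        for (name, start), stop in zip(self.events, bounds[1:]):
            out[name] = slice(start, stop)
        for name, sl in out.items():
            if sl.stop - sl.start < 1:
                raise ProtocolError(f"phase {name!r} contains no cycles")
        return out


@dataclass(frozen=True)
class NormalizationTable:
    """well_id → crystal-violet OD595 (proxy for adherent cell number)."""

    od595: Mapping[str, float]

    def value(self, well_id: str) -> float:
        try:
            v = self.od595[well_id]
        except KeyError:
            raise KeyError(f"well {well_id!r} missing from OD595 table") from None
        if v <= 0:
            raise ValueError(f"well {well_id!r}: OD595 must be > 0 (got {v}; empty/failed well)")
        return float(v)


def normalize_plate(plate: FluxPlate, od: NormalizationTable) -> FluxPlate:
    """Divide every OCR/ECAR value by its well's OD595."""
    if plate.normalised:
        raise ValueError("plate already normalised")
    factors = np.array([od.value(w) for w in plate.well_ids])[:, None]
    return FluxPlate(
        wells=plate.wells,
        cycles=plate.cycles,
        ocr=plate.ocr / factors,
        ecar=plate.ecar / factors,
        normalised=True,
    )


# default per-phase aggregators: basal is averaged; inhibitor phases take the
# extremum cycle, robust to the transient right after injection
DEFAULT_AGGREGATORS: dict[str, str] = {
    "basal": "mean",
    "oligomycin": "min",
    "fccp": "max",
    "antimycin_rotenone": "min",
    "monensin": "max",
}

_AGG_FUNCS = {"mean": np.mean, "min": np.min, "max": np.max, "median": np.median, "last": lambda a, axis: np.take(a, -1, axis=axis)}


@dataclass(frozen=True)
class PhaseSummary:
    """One aggregated rate per well per phase (units as the input plate)."""

    table: pd.DataFrame  # index well_id; basal_ocr, oligo_ocr, fccp_ocr, aarot_ocr, basal_ecar, monensin_ecar
    groups: pd.Series
    aggregators: Mapping[str, str]

    def require(self, *columns: str) -> None:
        missing = [c for c in columns if c not in self.table.columns]
        if missing:
            raise ValueError(f"phase summary missing {missing}")


_PHASE_COLUMNS = {
    "basal": [("basal_ocr", "ocr"), ("basal_ecar", "ecar")],
    "oligomycin": [("oligo_ocr", "ocr")],
    "fccp": [("fccp_ocr", "ocr")],
    "antimycin_rotenone": [("aarot_ocr", "ocr")],
    "monensin": [("monensin_ecar", "ecar")],
}


def summarize_phases(
    plate: FluxPlate,
    protocol: InjectionProtocol,
    aggregators: Mapping[str, str] | None = None,
) -> PhaseSummary:
    """Aggregate each well's trace to one rate per protocol phase."""
    agg = dict(DEFAULT_AGGREGATORS)
    if aggregators:
        agg.update(aggregators)
    phases = protocol.phases(len(plate.cycles))
    data: dict[str, np.ndarray] = {}
    for phase, sl in phases.items():
        fn = _AGG_FUNCS[agg[phase]]
        for col, signal in _PHASE_COLUMNS.get(phase, []):
            data[col] = fn(getattr(plate, signal)[:, sl], axis=1)
    table = pd.DataFrame(data, index=pd.Index(plate.well_ids, name="well_id"))
    return PhaseSummary(table=table, groups=plate.groups, aggregators=agg)


def respiratory_params(
    ps: PhaseSummary, subtract_nonmito_from_mrc: bool = False
) -> pd.DataFrame:
    """Mitochondrial stress-test parameters per well.

    ``ocr_mito = basal − non-mito``; ``ocr_coupled = basal − oligomycin``;
    ``ocr_leak = oligomycin − non-mito``; MRC is the raw post-FCCP OCR
    (optionally minus non-mitochondrial OCR); SRC = MRC − basal.  Negative
    derived rates are clamped to 0 and flagged (noise exceeding signal); the
    unclamped values are kept in ``*_raw`` diagnostic columns.
    """
    ps.require("basal_ocr", "oligo_ocr", "fccp_ocr", "aarot_ocr")
    t = ps.table
    out = pd.DataFrame(index=t.index)
    out["ocr_nonmito"] = t["aarot_ocr"]
    raw = {
        "ocr_mito": t["basal_ocr"] - t["aarot_ocr"],
        "ocr_coupled": t["basal_ocr"] - t["oligo_ocr"],
        "ocr_leak": t["oligo_ocr"] - t["aarot_ocr"],
    }
    clamped = pd.Series(0, index=t.index)
    for name, series in raw.items():
        out[name + "_raw"] = series
        out[name] = series.clip(lower=0.0)
        clamped += (series < 0).astype(int)
    # restore the exact decomposition after clamping
    out["ocr_mito"] = out["ocr_coupled"] + out["ocr_leak"]
    out["mrc"] = t["fccp_ocr"] - (t["aarot_ocr"] if subtract_nonmito_from_mrc else 0.0)
    src = out["mrc"] - t["basal_ocr"]
    out["src_raw"] = src
    out["src"] = src.clip(lower=0.0)
    clamped += (src < 0).astype(int)
    out["n_clamped"] = clamped
    out["flagged"] = clamped > 0
    return out


@dataclass(frozen=True)
class BioenergeticCoefficients:
    """Constants for converting OCR/ECAR to ATP production rates.

    Defaults describe glucose oxidation in a bicarbonate-free assay medium:

    * ``buffering_power`` — mpH per pmol H⁺ per well (medium-specific;
      strict mode requires an explicit value).
    * ``medium_ph`` / ``pk1`` — assay pH and carbonic-acid first pKa at
      37 °C, which set the CO₂ → H⁺ conversion fraction.
    * ``max_h_per_o2`` — protons released per O₂ for complete glucose
      oxidation.
    * ``atp_per_lactate`` — ATP per lactate exported (glycolytic
      substrate-level phosphorylation).
    * ``po_glyc`` — ATP per O from glycolysis coupled to pyruvate oxidation
      (2 ATP per glucose / 12 O).
    * ``po_oxphos`` / ``po_tca`` — ATP per O via oxidative phosphorylation
      and TCA-cycle substrate-level phosphorylation.
    """

    buffering_power: float = 0.1
    medium_ph: float = 7.4
    pk1: float = 6.093
    max_h_per_o2: float = 1.0
    atp_per_lactate: float = 1.0
    po_glyc: float = 0.167
    po_oxphos: float = 2.486
    po_tca: float = 0.121

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"coefficient {name} must be > 0 (got {value})")

    @property
    def co2_proton_fraction(self) -> float:
        """Fraction of respiratory CO₂ appearing as H⁺ at the assay pH."""
        r = 10.0 ** (self.medium_ph - self.pk1)
        return r / (1.0 + r)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "BioenergeticCoefficients":
        return cls(**dict(d))


def atp_fluxes(
    ps: PhaseSummary,
    rp: pd.DataFrame,
    coef: BioenergeticCoefficients,
) -> pd.DataFrame:
    """Decompose ATP production into glycolytic and oxidative rates.

    For state s ∈ {basal, max}::

        PPR_tot,s   = ECAR_s / buffering_power
        PPR_resp,s  = co2_proton_fraction × max_h_per_o2 × OCR_mito,s
        PPR_glyc,s  = max(PPR_tot,s − PPR_resp,s, 0)
        J_ATP_glyc,s = PPR_glyc,s × atp_per_lactate + OCR_mito,s × 2 × po_glyc
        J_ATP_ox,s   = OCR_coupled,s × 2 × po_oxphos + OCR_mito,s × 2 × po_tca

    Basal OCR terms come from the pre-injection phase; the maximal state
    takes ECAR from the monensin phase and OCR from the FCCP phase.  The
    glycolytic index is the basal glycolytic share of total ATP production,
    in percent; it is NaN (flagged) when total basal production is zero.
    """
    ps.require("basal_ocr", "basal_ecar", "oligo_ocr", "aarot_ocr", "fccp_ocr")
    t = ps.table
    out = pd.DataFrame(index=t.index)
    h_frac = coef.co2_proton_fraction

    def _state(ecar, ocr_mito, ocr_coupled, label):
        ppr_tot = ecar / coef.buffering_power
        ppr_resp = h_frac * coef.max_h_per_o2 * ocr_mito
        ppr_glyc = (ppr_tot - ppr_resp).clip(lower=0.0)
        j_glyc = ppr_glyc * coef.atp_per_lactate + ocr_mito * 2.0 * coef.po_glyc
        j_ox = ocr_coupled * 2.0 * coef.po_oxphos + ocr_mito * 2.0 * coef.po_tca
        out[f"j_atp_glyc_{label}"] = j_glyc
        out[f"j_atp_ox_{label}"] = j_ox
        out[f"j_atp_total_{label}"] = j_glyc + j_ox

    _state(t["basal_ecar"], rp["ocr_mito"], rp["ocr_coupled"], "basal")

    if "monensin_ecar" in t.columns:
        ocr_mito_max = (t["fccp_ocr"] - t["aarot_ocr"]).clip(lower=0.0)
        ocr_coupled_max = (t["fccp_ocr"] - t["oligo_ocr"]).clip(lower=0.0)
        _state(t["monensin_ecar"], ocr_mito_max, ocr_coupled_max, "max")
    else:  # no monensin phase: maximal glycolysis not elicited
        for col in ("j_atp_glyc_max", "j_atp_ox_max", "j_atp_total_max"):
            out[col] = np.nan

    total = out["j_atp_total_basal"]
    with np.errstate(invalid="ignore", divide="ignore"):
        gi = 100.0 * out["j_atp_glyc_basal"] / total
    gi[total <= 0] = np.nan
    out["glycolytic_index"] = gi
    out["dead_well"] = total <= 0
    return out


@dataclass(frozen=True)
class RatioReport:
    """Paired treated/control ratios with a one-sample test against 1."""

    ratios: np.ndarray
    mean: float
    sem: float
    t: float
    df: int
    p: float
    computable: bool
    reason: str = ""


def nutrient_stress_ratio(
    treated: Sequence[float], control: Sequence[float]
) -> RatioReport:
    """Per-replicate treated/control ratios (e.g. −Glc/+Glc) tested against 1.

    Replicates are paired by position.  A two-sided one-sample t-test asks
    whether the mean ratio differs from 1; with fewer than two replicates or
    zero variance the test is reported as not computable.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated and control must pair replicates 1:1")
    zero = np.nonzero(control == 0)[0]
    if zero.size:
        raise ValueError(f"control value 0 in replicate(s) {zero.tolist()}")
    ratios = treated / control
    n = ratios.size
    mean = float(ratios.mean()) if n else float("nan")
    sem = float(stats.sem(ratios)) if n >= 2 else float("nan")
    if n < 2:
        return RatioReport(ratios, mean, sem, np.nan, n - 1, np.nan, False, "n < 2")
    if np.isclose(ratios.std(ddof=1), 0.0):
        return RatioReport(ratios, mean, sem, np.nan, n - 1, np.nan, False, "zero variance")
    t, p = stats.ttest_1samp(ratios, popmean=1.0)
    return RatioReport(ratios, mean, sem, float(t), n - 1, float(p), True)


def star_code(p: float) -> str:
    """GraphPad-style significance stars at 0.05/0.01/0.001/0.0001."""
    if not np.isfinite(p):
        return "n/a"
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    method: str = "anova_tukey",
) -> dict:
    """Compare a per-well summary statistic between groups.

    ``method='anova_tukey'`` runs one-way ANOVA plus all-pairs Tukey HSD;
    ``method='student_t'`` runs a two-group Student's t-test.  Each pairwise
    comparison carries a star code at the 0.05/0.01/0.001/0.0001 thresholds.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    by_group = {g: values[groups == g] for g in labels}
    small = [g for g, v in by_group.items() if v.size < 2]
    if small:
        return {"method": method, "computable": False, "reason": f"groups with <2 observations: {small}"}

    if method == "student_t":
        if len(labels) != 2:
            raise ValueError("student_t requires exactly 2 groups")
        t, p = stats.ttest_ind(by_group[labels[0]], by_group[labels[1]])
        return {
            "method": method,
            "computable": True,
            "comparisons": [
                {"a": labels[0], "b": labels[1], "t": float(t), "p": float(p), "stars": star_code(p)}
            ],
        }
    if method != "anova_tukey":
        raise ValueError(f"unknown method {method!r}")
    if len(labels) < 2:
        raise ValueError("ANOVA requires >=2 groups")
    f, p = stats.f_oneway(*(by_group[g] for g in labels))
    tk = stats.tukey_hsd(*(by_group[g] for g in labels))
    comparisons = [
        {
            "a": str(labels[i]),
            "b": str(labels[j]),
            "p": float(tk.pvalue[i, j]),
            "stars": star_code(float(tk.pvalue[i, j])),
        }
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    return {
        "method": method,
        "computable": True,
        "anova_f": float(f),
        "anova_p": float(p),
        "comparisons": comparisons,
    }


def group_means(
    table: pd.DataFrame,
    groups: pd.Series,
    exclude_flagged: bool = True,
    flag_column: str = "flagged",
    max_clamped_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-group means of well-level summaries, with QC exclusion.

    Wells whose clamped-quantity fraction exceeds ``max_clamped_fraction``
    (default: more than half of the four derived rates clamped) are dropped
    from group means when ``exclude_flagged`` is set.
    """
    t = table.copy()
    if exclude_flagged and "n_clamped" in t.columns:
        keep = t["n_clamped"] / 4.0 <= max_clamped_fraction
        t = t[keep]
    numeric = t.select_dtypes(include=[np.number])
    return numeric.groupby(groups.reindex(numeric.index)).mean()
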