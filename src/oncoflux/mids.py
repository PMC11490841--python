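"""Natural-abundance correction of mass-isotopomer distributions (MIDs).

The forward model: a metabolite fragment with exactly ``j`` tracer-labelled
backbone carbons produces a distribution over observed mass shifts that is
the convolution of

* a binomial over the ``j`` labelled positions (tracer isotopic purity —
  an impure position falls back to 12C, i.e. shift 0),
* the natural 13C distribution of the remaining ``C - j`` carbons, and
* the natural heavy-isotope distributions of every non-carbon atom
  (H, N, O and, for silylated derivatives, Si).

Stacking these distributions as columns gives the correction matrix
``A``; a raw selected-ion-monitoring intensity vector ``m`` is corrected by
solving ``A x ≈ m`` under ``x ≥ 0`` and renormalising, yielding the MID.
Fractional 13C enrichment is then ``1 − x₀``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .isotopes import DEFAULT_ISOTOPES, FragmentSpec, IsotopeTable

__all__ = [
    "CorrectionMatrix",
    "MID",
    "LabellingMeasurement",
    "build_correction_matrix",
    "correct_mid",
    "total_enrichment",
    "isotopologue_ratio",
    "relative_abundance",
    "ratio_to_mean",
]

DEFAULT_TAIL = 4  # extra mass-shift rows beyond n_tracer_carbons (Si/O tail)


def _element_shift_pmf(shifts_fracs, n_atoms: int, r_max: int) -> np.ndarray:
    """Mass-shift distribution of ``n_atoms`` i.i.d. atoms, truncated at r_max.

    The single-atom pmf is convolved n_atoms times (fast repeated doubling is
    unnecessary at these sizes).  Mass beyond ``r_max`` is truncated, not
    renormalised — truncation is accounted for by the caller.
    """
    single = np.zeros(r_max + 1)
    truncated = 0.0
    for shift, frac in shifts_fracs:
        if shift <= r_max:
            single[shift] += frac
        else:
            truncated += frac
    out = np.zeros(r_max + 1)
    out[0] = 1.0
    for _ in range(n_atoms):
        out = np.convolve(out, single)[: r_max + 1]
    return out


@dataclass(frozen=True)
class CorrectionMatrix:
    """Theoretical mass-shift distributions per tracer-labelled count.

    ``matrix[r, j]`` = probability that a fragment with exactly ``j``
    labelled backbone carbons is observed at mass shift ``r``.  Columns sum
    to ≤ 1; the deficit is mass pushed beyond the retained row range and is
    recorded in ``truncated_mass``.
    """

    metabolite: str
    matrix: np.ndarray  # (R+1, N+1)
    n_tracer_carbons: int
    truncated_mass: np.ndarray  # per-column tail mass lost to truncation

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != self.n_tracer_carbons + 1:
            raise ValueError("correction matrix has wrong shape")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("correction-matrix entries outside [0, 1]")
        colsums = m.sum(axis=0)
        if np.any(colsums > 1 + 1e-9):
            raise ValueError("correction-matrix columns must sum to <= 1")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def build_correction_matrix(
    frag: FragmentSpec,
    iso: IsotopeTable = DEFAULT_ISOTOPES,
    tail: int = DEFAULT_TAIL,
) -> CorrectionMatrix:
    """Build the natural-abundance correction matrix for one fragment.

    Parameters
    ----------
    frag
        Fragment formula and tracer-carbon count.
    iso
        Isotope table (natural abundances + tracer purity).
    tail
        Extra rows retained beyond ``n_tracer_carbons``; heavy Si/O
        isotopes push measurable mass shifts past the labelled-carbon count.
    """
    n = frag.n_tracer_carbons
    r_max = n + tail
    total_c = frag.formula.get("C", 0)

    # shared non-tracer envelope: all non-C elements at natural abundance
    base = np.zeros(r_max + 1)
    base[0] = 1.0
    for el, count in frag.formula.items():
        if el == "C" or count == 0:
            continue
        pmf = _element_shift_pmf(iso.shifts_and_fractions(el), count, r_max)
        base = np.convolve(base, pmf)[: r_max + 1]

    c_pairs = iso.shifts_and_fractions(iso.tracer_element)
    purity = iso.tracer_purity

    cols = np.zeros((r_max + 1, n + 1))
    for j in range(n + 1):
        # natural abundance over the C - j unlabelled carbons
        col = np.convolve(base, _element_shift_pmf(c_pairs, total_c - j, r_max))[
            : r_max + 1
        ]
        # tracer purity over the j labelled positions: k of j actually 13C
        if j > 0:
            lab = binom.pmf(np.arange(0, min(j, r_max) + 1), j, purity)
            lab = np.pad(lab, (0, r_max + 1 - lab.size))
            col = np.convolve(col, lab)[: r_max + 1]
        cols[:, j] = col

    truncated = 1.0 - cols.sum(axis=0)
    return CorrectionMatrix(
        metabolite=frag.metabolite,
        matrix=cols,
        n_tracer_carbons=n,
        truncated_mass=np.clip(truncated, 0.0, None),
    )


@dataclass(frozen=True)
class MID:
    """Corrected mass-isotopomer distribution, fractions m+0 … m+N."""

    metabolite: str
    fractions: np.ndarray
    residual: float = 0.0
    condition_number: float = float("nan")
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.fractions, dtype=float)
        if np.any(x < -1e-12):
            raise ValueError("MID fractions must be non-negative")
        if abs(x.sum() - 1.0) > 1e-6:
            raise ValueError(f"MID fractions sum to {x.sum()!r}, not 1")

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i])

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class LabellingMeasurement:
    """Raw SIM intensities for one metabolite in one sample."""

    metabolite: str
    intensities: np.ndarray  # indexed by observed mass shift, m+0 ...
    internal_standard: float = float("nan")
    cell_count: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if np.any(v < 0):
            raise ValueError(f"{self.metabolite}: negative intensity")
        object.__setattr__(self, "intensities", v)


def correct_mid(
    meas: LabellingMeasurement,
    cm: CorrectionMatrix,
    condition_bound: float = 1e6,
) -> MID:
    """Invert the natural-abundance forward model for one measurement.

    Solves ``cm.matrix @ x ≈ intensities`` by non-negative least squares and
    renormalises ``x`` to sum 1.  The NNLS residual (relative to total
    intensity) and the matrix condition number are attached as diagnostics.
    """
    m = np.asarray(meas.intensities, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError(f"{meas.metabolite}: empty measurement (total intensity 0)")
    if m.size > cm.n_rows:
        m = m[: cm.n_rows]  # shifts beyond the modelled range carry no signal
    elif m.size < cm.n_rows:
        m = np.pad(m, (0, cm.n_rows - m.size))

    x, rnorm = nnls(cm.matrix, m / total)
    s = x.sum()
    if s <= 0:
        raise ValueError(f"{meas.metabolite}: correction produced an all-zero MID")
    warnings = []
    cond = cm.condition_number
    if cond > condition_bound:
        warnings.append(
            f"ill-conditioned correction matrix (cond={cond:.3g} > {condition_bound:.3g})"
        )
    return MID(
        metabolite=meas.metabolite,
        fractions=x / s,
        residual=float(rnorm),
        condition_number=cond,
        warnings=tuple(warnings),
    )


def total_enrichment(mid: MID) -> float:
    """Fractional 13C enrichment: 1 minus the unlabelled (m+0) fraction."""
    return float(np.clip(1.0 - mid[0], 0.0, 1.0))


def isotopologue_ratio(mid_a: MID, i: int, mid_b: MID, j: int) -> float:
    """Ratio mid_a[i] / mid_b[j]; NaN when the denominator is zero."""
    if not 0 <= i < len(mid_a):
        raise IndexError(f"index {i} out of range for {mid_a.metabolite}")
    if not 0 <= j < len(mid_b):
        raise IndexError(f"index {j} out of range for {mid_b.metabolite}")
    denom = mid_b[j]
    if denom == 0:
        return float("nan")
    return mid_a[i] / denom


def relative_abundance(meas: LabellingMeasurement) -> tuple[float, bool]:
    """Internal-standard- and cell-number-normalised relative abundance.

    Returns ``(value, cell_normalised)``: total ion intensity divided by the
    internal-standard intensity, then by cell count when available.  When the
    cell count is missing the un-normalised value is returned flagged.
    """
    is_int = meas.internal_standard
    if not np.isfinite(is_int) or is_int <= 0:
        raise ValueError(
            f"{meas.metabolite}: internal-standard intensity must be > 0 "
            "(zero signals failed derivatization)"
        )
    value = float(meas.intensities.sum() / is_int)
    if meas.cell_count is None:
        return value, False
    if meas.cell_count <= 0:
        raise ValueError(f"{meas.metabolite}: cell count must be > 0")
    return value / meas.cell_count, True


def ratio_to_mean(abundances: "np.ndarray | object") -> "object":
    """log2 ratio of each value to its row (metabolite) arithmetic mean.

    Accepts a metabolite × sample array or DataFrame; every entry must be
    strictly positive (no silent pseudocounts).
    """
    import pandas as pd

    values = np.asarray(
        abundances.values if isinstance(abundances, pd.DataFrame) else abundances,
        dtype=float,
    )
    bad = np.argwhere(~(values > 0))
    if bad.size:
        r, c = bad[0]
        if isinstance(abundances, pd.DataFrame):
            raise ValueError(
                f"non-positive abundance at metabolite {abundances.index[r]!r}, "
                f"sample {abundances.columns[c]!r}"
            )
        raise ValueError(f"non-positive abundance at row {r}, column {c}")
    out = np.log2(values / values.mean(axis=1, keepdims=True))
    if isinstance(abundances, pd.DataFrame):
        return pd.DataFrame(out, index=abundances.index, columns=abundances.columns)
    return out
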