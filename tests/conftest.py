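import itertools

import numpy as np
import pytest

from oncoflux.isotopes import DEFAULT_ISOTOPES, FragmentSpec, default_fragment_registry


@pytest.fixture(scope="session")
def registry():
    return default_fragment_registry()


@pytest.fixture(scope="session")
def iso():
    return DEFAULT_ISOTOPES


def brute_force_columns(frag: FragmentSpec, iso, r_max: int) -> np.ndarray:
    """Exhaustive enumeration oracle for the correction matrix.

    Enumerates every per-atom isotope assignment of the fragment (tracer
    positions included) and accumulates probability mass by total mass
    shift.  Exponential in atom count — only usable for tiny fragments.
    """
    n = frag.n_tracer_carbons
    atoms_common: list[tuple[tuple[int, float], ...]] = []
    for el, count in frag.formula.items():
        natural = tuple(iso.abundances[el])
        n_natural = count - (n if el == "C" else 0)
        atoms_common.extend([natural] * n_natural)
    tracer_options = ((1, iso.tracer_purity), (0, 1.0 - iso.tracer_purity))

    cols = np.zeros((r_max + 1, n + 1))
    for j in range(n + 1):
        # j labelled positions follow tracer purity, n-j backbone positions natural
        atoms = atoms_common + [tracer_options] * j + [tuple(iso.abundances["C"])] * (n - j)
        for combo in itertools.product(*atoms):
            shift = sum(s for s, _ in combo)
            if shift <= r_max:
                prob = 1.0
                for _, p in combo:
                    prob *= p
                cols[shift, j] += prob
    return cols


@pytest.fixture(scope="session")
def oracle():
    return brute_force_columns
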