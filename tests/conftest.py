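import numpy as np
import pytest

from lipidnet.msio import Spectrum
from lipidnet.synthetic import SimConfig, noiseless, simulate_dataset, standard_mix


@pytest.fixture(scope="session")
def mix_species():
    return standard_mix()


@pytest.fixture(scope="session")
def noiseless_config():
    return noiseless(SimConfig(seed=0))


@pytest.fixture(scope="session")
def standard_dataset():
    """The 65-standard mixture simulated under default noise."""
    return simulate_dataset(standard_mix(), SimConfig(seed=7))


def random_spectrum_pair(rng, max_peaks=12, grid=0.5):
    """A random spectrum pair with deliberate peak/neutral-loss overlap.

    m/z values snap to a coarse grid so direct and precursor-shifted
    matches (and assignment conflicts) actually occur.
    """
    def peaks(n, offset=0.0):
        mz = np.sort(rng.choice(np.arange(100.0, 500.0, grid),
                                size=n, replace=False)) + offset
        inten = rng.uniform(1.0, 100.0, size=n)
        return mz, inten

    na = int(rng.integers(2, max_peaks + 1))
    nb = int(rng.integers(2, max_peaks + 1))
    prec_a = 700.0 + grid * int(rng.integers(0, 20))
    prec_b = 700.0 + grid * int(rng.integers(0, 20))
    mza, ia = peaks(na)
    # part of b mirrors a (directly or shifted), part is fresh
    mzb, ib = peaks(nb)
    n_copy = int(rng.integers(0, min(na, nb) + 1))
    if n_copy:
        shift = (prec_b - prec_a) if rng.random() < 0.5 else 0.0
        mzb[:n_copy] = mza[rng.choice(na, n_copy, replace=False)] + shift
    a = Spectrum(id="a", precursor_mz=prec_a, mz=mza, intensity=ia)
    b = Spectrum(id="b", precursor_mz=prec_b, mz=mzb, intensity=ib)
    return a, b


def exhaustive_modified_cosine(a, b, fragment_tol=0.02, use_shift=True):
    """Brute-force optimal one-to-one peak assignment (oracle).

    Enumerates every conflict-free subset of candidate peak pairs by
    backtracking; independent of the production implementation.
    """
    wa = np.sqrt(a.intensity); wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensity); wb = wb / np.linalg.norm(wb)
    pairs = []
    shift = a.precursor_mz - b.precursor_mz
    for i in range(a.mz.size):
        for j in range(b.mz.size):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= fragment_tol or (
                    use_shift and abs(shift) > fragment_tol
                    and abs(d - shift) <= fragment_tol):
                pairs.append((i, j, wa[i] * wb[j]))

    best = [0.0]

    def recurse(k, used_i, used_j, score):
        best[0] = max(best[0], score)
        if k == len(pairs):
            return
        remaining = sum(p[2] for p in pairs[k:])
        if score + remaining <= best[0]:
            return
        i, j, w = pairs[k]
        if i not in used_i and j not in used_j:
            recurse(k + 1, used_i | {i}, used_j | {j}, score + w)
        recurse(k + 1, used_i, used_j, score)

    recurse(0, frozenset(), frozenset(), 0.0)
    return min(best[0], 1.0)
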