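import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from medipgmr.synthetic_data import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """A small planted cohort shared by tests that only need valid inputs."""
    cfg = SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length=400_000,
        n_genes=20,
        n_case_dmrs=2,
        n_env_dmrs=1,
        n_pmds=1,
        pmd_length=150_000,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale planted cohort (shared: simulation is the slow part)."""
    return simulate_cohort(SimulationConfig(seed=3))


def brute_force_regions(depth_matrix: np.ndarray, min_len: int = 200,
                        merge_gap: int = 200, chunk: int = 4000):
    """Nucleotide-stepping oracle for read-covered region construction.

    Walks the chromosome position by position, closing gaps shorter than
    *merge_gap*, then drops short runs and splits long ones with an explicit
    while-loop.  Returns a list of (start, end) tuples.
    """
    n_cows, length = depth_matrix.shape
    merged = []
    run_start = None
    last_covered = None
    for pos in range(length):
        covered = any(depth_matrix[c, pos] > 0 for c in range(n_cows))
        if covered:
            if run_start is None:
                run_start = pos
            elif pos - (last_covered + 1) >= merge_gap:
                merged.append((run_start, last_covered + 1))
                run_start = pos
            last_covered = pos
    if run_start is not None:
        merged.append((run_start, last_covered + 1))
    merged = [(s, e) for s, e in merged if e - s >= min_len]
    pieces = []
    for s, e in merged:
        while e - s > chunk:
            if (e - s) - chunk < min_len:
                break
            pieces.append((s, s + chunk))
            s += chunk
        pieces.append((s, e))
    return pieces


def brute_force_position_map(k: int, L: int) -> list[int]:
    """Whole-element oracle for length standardization.

    Builds the full assignment of element nucleotides 1..k to standardized
    slots by explicit list construction instead of a per-index formula.
    """
    if k >= L:
        half = L // 2
        head = list(range(1, half + 1))
        middle = [half + 1] * (k - 2 * half)
        tail = list(range(L - half + 1, L + 1))
        return head + middle + tail
    h = (k + 1) // 2
    return list(range(1, h + 1)) + list(range(L - (k - h) + 1, L + 1))
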