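import pytest
from hypothesis import settings

from epitile.demo import demo_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from epitile.longitudinal import detect_induced
from epitile.panel import build_peptide_index, tile_panel
from epitile.reactivity import call_reactive, robust_z
from epitile.synthetic import evaluate_recovery, simulate_cohort


@pytest.fixture(scope="session")
def demo():
    """Synthetic 21-record demonstration panel plus its master alignment."""
    return demo_panel()


@pytest.fixture(scope="session")
def demo_tiles(demo):
    panel, alignment = demo
    return tile_panel(panel, k=16, offset=1, alignment=alignment)


@pytest.fixture(scope="session")
def demo_index(demo_tiles):
    return build_peptide_index(demo_tiles)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast down-scaled cohort for unit tests (6 subjects, 8 isoforms)."""
    return simulate_cohort(
        seed=7,
        n_allergens=8,
        length=80,
        n_subjects=6,
        epitopes_per_subject=2,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort with its full pipeline outputs."""
    panel, alignment, tiles, truth, matrix = simulate_cohort(seed=1)
    z = robust_z(matrix)
    calls = call_reactive(z, tiles)
    induced = detect_induced(z, matrix.log2, tiles, calls=calls)
    metrics = evaluate_recovery(
        truth, tiles, calls, induced_events=induced, matrix=matrix,
        alignment=alignment,
    )
    return {
        "panel": panel,
        "alignment": alignment,
        "tiles": tiles,
        "truth": truth,
        "matrix": matrix,
        "z": z,
        "calls": calls,
        "induced": induced,
        "metrics": metrics,
    }
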