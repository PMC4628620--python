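import numpy as np
import pytest

from ecgherit.ecg_traits import EcgRecord, LEADS
from ecgherit.pedigree import compute_kinship, validate_pedigree
from ecgherit.synthetic_data import SimulationConfig, simulate_pedigree


@pytest.fixture
def trio_rows():
    return [("F", "0", "0", "1"), ("M", "0", "0", "2"), ("C", "F", "M", "1")]


@pytest.fixture
def trio_ped(trio_rows):
    return validate_pedigree(trio_rows)


@pytest.fixture
def cousin_ped():
    """Two sibships whose children (first cousins) mate; their child is inbred."""
    rows = [
        ("GF", "0", "0", "1"), ("GM", "0", "0", "2"),
        ("A", "GF", "GM", "1"), ("B", "GF", "GM", "2"),
        ("WA", "0", "0", "2"), ("HB", "0", "0", "1"),
        ("CA", "A", "WA", "1"), ("CB", "HB", "B", "2"),
        ("X", "CA", "CB", "1"),
    ]
    return validate_pedigree(rows)


@pytest.fixture
def three_gen_rows():
    """3-generation, 20-individual pedigree (deterministic)."""
    rows = [(f"F{k}", "0", "0", "1" if k % 2 == 0 else "2") for k in range(8)]
    for k in range(4):  # generation 1: 8 children of 4 founder couples
        fa, mo = f"F{2 * k}", f"F{2 * k + 1}"
        rows += [(f"G{2 * k}", fa, mo, "1"), (f"G{2 * k + 1}", fa, mo, "2")]
    # generation 2: children of cross-couple matings
    rows += [
        ("H0", "G0", "G3", "1"), ("H1", "G0", "G3", "2"),
        ("H2", "G4", "G7", "1"), ("H3", "G4", "G7", "2"),
    ]
    return rows


@pytest.fixture
def small_sim_ped():
    """Random pedigree of a few hundred individuals for fitter tests."""
    cfg = SimulationConfig(n_founders=30, n_generations=3, seed=11)
    return simulate_pedigree(cfg, np.random.default_rng(11))


@pytest.fixture
def small_sim_kin(small_sim_ped):
    return compute_kinship(small_sim_ped)


def make_record(
    iid="r1",
    qrs=100.0,
    qt=400.0,
    pr=160.0,
    hr=60.0,
    axis=30.0,
    amp=None,
    flags=None,
):
    if amp is None:
        amp = {lead: (1.0, 1.0) for lead in LEADS}
    return EcgRecord(
        id=iid, qrs_ms=qrs, qt_ms=qt, pr_ms=pr, heart_rate_bpm=hr,
        qrs_axis_deg=axis, amp=amp, flags=flags or {},
    )
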