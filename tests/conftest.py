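import numpy as np
import pytest

import protscape as ps


@pytest.fixture(scope="session")
def ref_table() -> ps.ShapeTable:
    """Bundled synthetic reference ProT table (1024 pentamers)."""
    return ps.load_reference_table()


@pytest.fixture(scope="session")
def mini_table() -> ps.ShapeTable:
    """Two-entry table closed under reverse complementation."""
    return ps.ShapeTable.from_entries({"AAAAA": -13.0, "GCGCG": -1.0}, "ProT")


def brute_force_track(sequence: str, table: ps.ShapeTable) -> np.ndarray:
    """Independent per-position pentamer enumerator (the oracle for the
    sliding-window engine)."""
    seq = sequence.upper()
    L = len(seq)
    values = np.full(L, np.nan)
    for i in range(2, L - 2):
        pent = seq[i - 2 : i + 3]
        if any(b not in "ACGT" for b in pent):
            continue
        values[i] = table.value(pent)
    return values


@pytest.fixture(scope="session")
def wlc_sample():
    """Kink-free worm-like chains at the reference persistence length.

    Shared across polymer tests: 600 molecules, P = 55 nm, contour 340 nm,
    spacing 2.5 nm.
    """
    traces = ps.simulate_wlc_2d(55.0, 340.0, 2.5, 600, seed=1226)
    angles = ps.bend_angles(traces, separation=5.0)
    return traces, angles


@pytest.fixture(scope="session")
def enhancer_pipeline(ref_table):
    """Default-condition enhancer genome with its tracks and feature sets."""
    cfg = ps.GeneratorConfig(seed=5)
    genome = ps.gen_enhancer_genome(cfg, ref_table)
    tracks = ps.predict_tracks(genome.sequences, ref_table)
    return cfg, genome, tracks
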