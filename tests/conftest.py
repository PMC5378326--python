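import numpy as np
import pandas as pd
import pytest

import deltol as dt


def make_pdb_line(
    serial, name, resname, chain, resnum, x, y, z,
    occ=1.0, altloc=" ", element=None, record="ATOM",
):
    """Format one fixed-width PDB ATOM/HETATM record."""
    if element is None:
        element = name[0]
    padded = f" {name}" if len(name) < 4 and len(element) == 1 else name
    return (
        f"{record:<6s}{serial:5d} {padded:<4s}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def minimal_pdb():
    return make_pdb_line(1, "CA", "ALA", "A", 5, 1.0, 2.0, 3.0) + "\nEND\n"


@pytest.fixture
def toy_structure():
    """5 pseudo-residues at controlled positions, including a glycine."""
    return dt.synth_structure(5, seed=11)


@pytest.fixture(scope="session")
def default_table():
    """The default study-shaped synthetic table (72 mutants, 34 tolerated)."""
    table, truth = dt.synth_feature_table(dt.SynthParams(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def small_table():
    """A small signal-bearing table for fast model smoke tests."""
    table, _ = dt.synth_feature_table(dt.SynthParams(n_mutants=40, seed=7))
    return table


def wcn_bruteforce(points):
    """Independent O(N^2) double-loop WCN oracle."""
    n = len(points)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = np.sqrt(sum((points[i][k] - points[j][k]) ** 2
                                for k in range(3)))
                out[i] += 1.0 / d**2
    return out


def welch_oracle(a, b):
    """Textbook Welch t-test (statistic, dof, two-sided p)."""
    import scipy.stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * scipy.stats.t.sf(abs(t), dof)
    return t, dof, p
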