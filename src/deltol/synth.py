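"""Synthetic structures, score sets and feature tables with known ground truth.

Every generator is fully deterministic under a fixed seed.  The default
feature-table parameters emulate the qualitative structure of the eGFP
deletion dataset: 72 mutants split 34 tolerated / 38 non-tolerated, with
the tolerated class more solvent-exposed (higher RSA), less tightly packed
(lower WCN), energetically more favorable (more negative mean design
score) and enriched in loops, while the non-tolerated class is enriched in
beta sheets.  The numeric locations and scales are package choices tuned
only for qualitative realism, not measured values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .exceptions import PackingError
from .features import FEATURE_COLUMNS
from .structure import Atom, CenterPoint, Residue, Structure

logger = logging.getLogger(__name__)

SS_ORDER = ("loop", "helix", "sheet")

#: (location, scale) per functional class, keys "tolerated"/"non_tolerated".
ClassDist = dict[str, tuple[float, float]]


def synth_point_cloud(
    n: int,
    box: float = 30.0,
    min_separation: float = 2.0,
    seed: int = 0,
    max_attempts_per_point: int = 1000,
) -> list[CenterPoint]:
    """``n`` random points in a cubic box with a minimum pairwise distance.

    A rejection-sampled substrate for WCN tests (the separation guarantees
    no singular 1/r**2 terms).  Deterministic per seed.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    for i in range(n):
        for _ in range(max_attempts_per_point):
            cand = rng.uniform(0.0, box, size=3)
            if all(
                np.linalg.norm(cand - p) >= min_separation for p in points
            ):
                points.append(cand)
                break
        else:
            raise PackingError(
                f"could not place point {i + 1}/{n} with separation "
                f">= {min_separation} in a box of {box} A"
            )
    return [
        CenterPoint(
            residue_key=("A", i + 1, ""), point=p, method="sidechain_geometric"
        )
        for i, p in enumerate(points)
    ]


_SYNTH_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)
_SIDE_CHAIN_NAMES = ("CB", "CG", "CD", "CE")


def synth_structure(
    n_residues: int,
    seed: int = 0,
    glycine_fraction: float = 0.1,
    step: float = 3.8,
    min_separation: float = 3.5,
) -> Structure:
    """A compact pseudo-protein: a self-avoiding C-alpha walk with pseudo
    side chains.

    Each residue carries a C-alpha plus one to four carbon side-chain
    pseudo-atoms built outward from it; residues flagged as glycine carry
    no side-chain atoms.  The walk is confined to a sphere so interior and
    surface residues exist, and the result is valid, round-trippable PDB.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    r_max = 2.8 * n_residues ** (1.0 / 3.0) + 3.0

    for _restart in range(100):
        ca = [np.zeros(3)]
        ok = True
        for _ in range(n_residues - 1):
            for _try in range(300):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = ca[-1] + step * direction
                if np.linalg.norm(cand) > r_max:
                    continue
                if all(
                    np.linalg.norm(cand - p) >= min_separation
                    for p in ca[:-1]
                ):
                    ca.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise PackingError("could not build a self-avoiding backbone walk")

    residues = []
    for i, pos in enumerate(ca):
        is_gly = rng.random() < glycine_fraction
        atoms = [Atom(name="CA", element="C", position=pos)]
        if is_gly:
            name = "GLY"
        else:
            name = _SYNTH_AA[rng.integers(len(_SYNTH_AA))]
            n_side = int(rng.integers(1, 5))
            prev = pos
            for atom_name in _SIDE_CHAIN_NAMES[:n_side]:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                prev = prev + 1.5 * direction
                atoms.append(
                    Atom(name=atom_name, element="C", position=prev)
                )
        residues.append(
            Residue(
                chain_id="A",
                number=i + 1,
                insertion_code="",
                name=name,
                atoms=atoms,
            )
        )
    return Structure(id=f"synth{n_residues}", residues=residues)


@dataclass
class SynthParams:
    """Ground-truth parameters of the synthetic feature-table generator.

    ``label_mode`` selects how labels arise:

    - ``class_conditional``: a fixed tolerated count (``label_split`` of
      ``n_mutants``) with per-class feature distributions — mimics the
      observed-data situation where group contrasts are the target;
    - ``logistic``: features drawn first (class-averaged distributions),
      labels Bernoulli from the configured logistic model — the ground
      truth needed for coefficient-recovery tests.
    """

    n_mutants: int = 72
    label_split: float = 34 / 72
    label_mode: str = "class_conditional"
    # default weights are centered on the default feature locations so the
    # logistic mode yields a roughly balanced label split
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "const": -38.23, "rsa": 2.0, "wcn": -20.0, "mean_score": -0.08,
        }
    )
    rsa_distributions: ClassDist = field(
        default_factory=lambda: {
            "tolerated": (0.45, 0.20), "non_tolerated": (0.22, 0.15),
        }
    )
    wcn_distributions: ClassDist = field(
        default_factory=lambda: {
            "tolerated": (0.10, 0.030), "non_tolerated": (0.16, 0.035),
        }
    )
    score_distributions: ClassDist = field(
        default_factory=lambda: {
            "tolerated": (-510.0, 8.0), "non_tolerated": (-494.0, 10.0),
        }
    )
    ss_probabilities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {  # (loop, helix, sheet)
            "tolerated": (0.55, 0.20, 0.25),
            "non_tolerated": (0.18, 0.10, 0.72),
        }
    )
    n_models_per_mutant: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.label_split < 1.0:
            raise ValueError("label_split must be in (0, 1)")
        if self.label_mode not in ("class_conditional", "logistic"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        for cls, probs in self.ss_probabilities.items():
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(
                    f"ss probabilities for {cls!r} must be a distribution"
                )
        for dists in (
            self.rsa_distributions,
            self.wcn_distributions,
            self.score_distributions,
        ):
            for cls, (_, scale) in dists.items():
                if scale <= 0:
                    raise ValueError(f"scale for {cls!r} must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows: the parameters and, in logistic mode, the
    per-row linear predictor and success probability."""

    params: SynthParams
    n_tolerated: int
    linear_predictor: Optional[np.ndarray] = None
    probabilities: Optional[np.ndarray] = None


def _class_average(dist: ClassDist) -> tuple[float, float]:
    (l1, s1) = dist["tolerated"]
    (l2, s2) = dist["non_tolerated"]
    return (0.5 * (l1 + l2), 0.5 * (s1 + s2))


def synth_feature_table(
    params: Optional[SynthParams] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a feature table plus its ground-truth record.

    Column layout matches the observed-data feature table:
    ``mutant_id, rsa, wcn, ss, mean_score, functional``.
    """
    if params is None:
        params = SynthParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_mutants

    if params.label_mode == "class_conditional":
        n_tol = int(round(params.label_split * n))
        labels = np.zeros(n, dtype=bool)
        labels[rng.permutation(n)[:n_tol]] = True
        rsa_v = np.empty(n)
        wcn_v = np.empty(n)
        score_v = np.empty(n)
        ss_v = np.empty(n, dtype=object)
        for cls, mask in (
            ("tolerated", labels), ("non_tolerated", ~labels)
        ):
            m = int(mask.sum())
            loc, scale = params.rsa_distributions[cls]
            rsa_v[mask] = rng.normal(loc, scale, size=m)
            loc, scale = params.wcn_distributions[cls]
            wcn_v[mask] = rng.normal(loc, scale, size=m)
            loc, scale = params.score_distributions[cls]
            score_v[mask] = rng.normal(loc, scale, size=m)
            ss_v[mask] = rng.choice(
                SS_ORDER, size=m, p=params.ss_probabilities[cls]
            )
        truth = GroundTruth(params=params, n_tolerated=n_tol)
    else:  # logistic
        loc, scale = _class_average(params.rsa_distributions)
        rsa_v = rng.normal(loc, scale, size=n)
        loc, scale = _class_average(params.wcn_distributions)
        wcn_v = rng.normal(loc, scale, size=n)
        loc, scale = _class_average(params.score_distributions)
        score_v = rng.normal(loc, scale, size=n)
        p_loop, p_helix, p_sheet = np.mean(
            [
                params.ss_probabilities["tolerated"],
                params.ss_probabilities["non_tolerated"],
            ],
            axis=0,
        )
        ss_v = rng.choice(SS_ORDER, size=n, p=(p_loop, p_helix, p_sheet))
        columns = {
            "rsa": rsa_v,
            "wcn": wcn_v,
            "mean_score": score_v,
            "ss_loop": (ss_v == "loop").astype(float),
            "ss_helix": (ss_v == "helix").astype(float),
            "ss_sheet": (ss_v == "sheet").astype(float),
        }
        eta = np.full(n, params.coefficients.get("const", 0.0))
        for name, coef in params.coefficients.items():
            if name == "const":
                continue
            if name not in columns:
                raise ValueError(f"unknown coefficient name {name!r}")
            eta = eta + coef * columns[name]
        prob = expit(eta)
        labels = rng.random(n) < prob
        truth = GroundTruth(
            params=params,
            n_tolerated=int(labels.sum()),
            linear_predictor=eta,
            probabilities=prob,
        )

    table = pd.DataFrame(
        {
            "mutant_id": [f"mut{i + 1:03d}" for i in range(n)],
            "rsa": rsa_v,
            "wcn": wcn_v,
            "ss": ss_v,
            "mean_score": score_v,
            "functional": labels,
        },
        columns=FEATURE_COLUMNS,
    )
    return table, truth


def binormal_scores(
    n_neg: int,
    n_pos: int,
    mu_neg: float = 0.0,
    mu_pos: float = 1.0,
    sd_neg: float = 1.0,
    sd_pos: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Class-conditional normal scores with a closed-form theoretical AUC.

    Returns ``(scores, labels, auc_theory)`` with
    ``auc_theory = Phi((mu_pos - mu_neg) / sqrt(sd_neg**2 + sd_pos**2))``.
    """
    if sd_neg <= 0 or sd_pos <= 0:
        raise ValueError("standard deviations must be > 0")
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(mu_neg, sd_neg, n_neg), rng.normal(mu_pos, sd_pos, n_pos)]
    )
    labels = np.concatenate(
        [np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)]
    )
    auc_theory = float(
        norm.cdf((mu_pos - mu_neg) / np.sqrt(sd_neg**2 + sd_pos**2))
    )
    return scores, labels, auc_theory


def synth_score_files(
    mutant_ids: Sequence[str],
    class_labels: Sequence[bool],
    params: Optional[SynthParams] = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> dict[str, float]:
    """Write one design-score table per mutant and return the written means.

    Each file (``<mutant_id>.sc``, whitespace-delimited with a
    ``total_score`` column) holds ``params.n_models_per_mutant`` normal
    draws from that mutant's class distribution — tolerated mutants score
    lower (more negative) under the defaults.
    """
    if params is None:
        params = SynthParams()
    if len(mutant_ids) != len(class_labels):
        raise ValueError("mutant_ids and class_labels must align")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    means: dict[str, float] = {}
    for mid, tolerated in zip(mutant_ids, class_labels):
        cls = "tolerated" if tolerated else "non_tolerated"
        loc, scale = params.score_distributions[cls]
        draws = rng.normal(loc, scale, size=params.n_models_per_mutant)
        lines = ["total_score description"]
        for j, v in enumerate(draws):
            lines.append(f"{float(v)!r} {mid}_{j + 1:04d}")
        (out_dir / f"{mid}.sc").write_text("\n".join(lines) + "\n")
        means[mid] = float(draws.mean())
    return means
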