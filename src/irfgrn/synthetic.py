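"""Synthetic expression profiles and random test networks.

The expression generator emulates the statistical structure of a two-cytokine
Langerhans-cell time course on the linear RMA-like intensity scale: TNFa
induces IRF1 and IRF8 (6.7- and 13.5-fold at 2 h), TSLP induces IRF4
(4-fold default), inductions peak at 2 h and decay geometrically to 24 h,
multiplicative log-normal noise, and AP-1/ETS partner baselines straddling
the 150-intensity inclusion threshold.  Output genes follow their programme
truth: Programme A genes rise under TNFa only, Programme B genes rise under
both cytokines.

It does not emulate probe-level microarray noise, batch effects or RMA
preprocessing; see the methods note for what that implies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AP1_PARTNERS,
    ETS_PARTNERS,
    PROGRAMME_A_GENES,
    PROGRAMME_B_GENES,
    PetriNetModel,
    Place,
    Transition,
)
from .parameterize import ExpressionProfile

CONDITIONS = ("TNFa", "TSLP")
TIME_POINTS = (0, 2, 8, 24)

#: linear-intensity baselines; partner families deliberately straddle the
#: 150 inclusion threshold (below: BATF3, ELK3, EHF, ETV3)
DEFAULT_BASELINES = {
    "IRF1": 120.0, "IRF8": 110.0, "IRF4": 100.0,
    "JUN": 500.0, "FOS": 450.0, "BATF": 200.0, "BATF3": 110.0,
    "ELF1": 400.0, "ELF4": 300.0, "ELK1": 250.0, "ELK3": 130.0,
    "ETS1": 350.0, "ETS2": 280.0, "EHF": 90.0, "ELF2": 260.0,
    "ETV3": 120.0, "ETV6": 310.0, "GABPA": 240.0,
}

DEFAULT_FOLDS = {
    ("IRF1", "TNFa"): 6.7,
    ("IRF8", "TNFa"): 13.5,
    ("IRF4", "TSLP"): 4.0,
}
#: fold multipliers for output genes driven by their programme
_A_GENE_FOLD = 8.0
_B_GENE_FOLD = 5.0

#: induction peaks at 2 h, then decays geometrically towards baseline
DEFAULT_DECAY = {2.0: 1.0, 8.0: 0.5, 24.0: 0.25}


@dataclass
class GeneratorParams:
    baselines: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    decay_profile: dict[float, float] = field(default_factory=dict)
    noise_sigma: float = 0.1
    programme_truth: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.baselines.values()):
            raise ValueError("baselines must be > 0")
        if any(v <= 0 for v in self.fold_changes.values()):
            raise ValueError("fold changes must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_params(noise_sigma: float = 0.1, seed: int = 0) -> GeneratorParams:
    """Study-condition defaults covering every entry TF, partner and output."""
    baselines = dict(DEFAULT_BASELINES)
    folds = dict(DEFAULT_FOLDS)
    truth = {}
    for g in PROGRAMME_A_GENES:
        baselines[g] = 100.0
        folds[(g, "TNFa")] = _A_GENE_FOLD
        truth[g] = "A"
    for g in PROGRAMME_B_GENES:
        baselines[g] = 100.0
        folds[(g, "TNFa")] = _B_GENE_FOLD
        folds[(g, "TSLP")] = _B_GENE_FOLD
        truth[g] = "B"
    return GeneratorParams(
        baselines=baselines, fold_changes=folds,
        decay_profile=dict(DEFAULT_DECAY),
        noise_sigma=noise_sigma, programme_truth=truth, seed=seed,
    )


def _fold_at(params: GeneratorParams, gene: str, condition: str,
             time_point: float) -> float:
    if time_point == 0:
        return 1.0
    peak = params.fold_changes.get((gene, condition), 1.0)
    decay = params.decay_profile.get(float(time_point), 1.0)
    return 1.0 + (peak - 1.0) * decay


def generate_expression(params: GeneratorParams) -> ExpressionProfile:
    """Intensity(g, c, t) = baseline(g) x fold(g, c, t) x LogNormal(0, sigma)."""
    rng = np.random.default_rng(params.seed)
    genes = list(params.baselines)
    columns = [f"{c}_{t}h" for c in CONDITIONS for t in TIME_POINTS]
    data = np.empty((len(genes), len(columns)))
    for i, gene in enumerate(genes):
        j = 0
        for condition in CONDITIONS:
            for t in TIME_POINTS:
                expected = params.baselines[gene] * _fold_at(
                    params, gene, condition, t
                )
                noise = (
                    rng.lognormal(0.0, params.noise_sigma)
                    if params.noise_sigma > 0 else 1.0
                )
                data[i, j] = expected * noise
                j += 1
    frame = pd.DataFrame(data, index=genes, columns=columns)
    frame.index.name = "gene"
    return ExpressionProfile(frame)


def expected_intensity(params: GeneratorParams, gene: str, condition: str,
                       time_point: float) -> float:
    """Noise-free intensity, for tests and calibration."""
    return params.baselines[gene] * _fold_at(params, gene, condition, time_point)


def generate_random_small_net(n_places: int, n_transitions: int,
                              seed: int = 0) -> PetriNetModel:
    """Random acyclic-from-entries bipartite net (no inhibitors).

    Entries occupy the lowest indices and transitions only point from lower
    to higher place indices, so the net is a DAG with >=1 entry and >=1
    output; a test fixture for the oracle-equivalence property.
    """
    if n_places < 2:
        raise ValueError("need at least 2 places")
    if n_transitions < 1:
        raise ValueError("need at least 1 transition")
    rng = np.random.default_rng(seed)
    n_entry = max(1, n_places // 3)
    n_out = max(1, n_places // 4)
    if n_entry + n_out > n_places:
        n_out = n_places - n_entry
    places = []
    for i in range(n_places):
        if i < n_entry:
            places.append(Place(f"p{i}", klass="transcription_factor",
                                is_entry=True))
        elif i >= n_places - n_out:
            places.append(Place(f"p{i}", klass="output_gene", is_output=True))
        else:
            places.append(Place(f"p{i}", klass="complex"))
    transitions = []
    for j in range(n_transitions):
        o = int(rng.integers(n_entry, n_places))
        k = int(rng.integers(1, min(2, o) + 1))
        inputs = sorted(int(x) for x in rng.choice(o, size=k, replace=False))
        transitions.append(Transition(
            id=f"t{j}",
            activating_inputs=tuple(f"p{i}" for i in inputs),
            outputs=(f"p{o}",),
        ))
    return PetriNetModel(places, transitions,
                         {"name": f"random-net-{n_places}p-{n_transitions}t-s{seed}"})
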