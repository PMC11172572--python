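"""Latent-space molecule optimization toward lower predicted GI50.

Seeds (either the top-k most potent training molecules or a user list of
clinically used drugs) are encoded noise-free into the flow latent
space; plain gradient descent on the GI50 head,

    z_{t+1} = z_t - eta * grad predict(z_t),

is run for several step sizes eta ("jumps of varying distance"); every
iterate is decoded back to a molecule and annotated with its predicted
GI50, normalized synthetic-accessibility score and Tanimoto similarity
to the seed.  The flow and head stay frozen throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemgraph import graph_to_smiles, normalized_sas, smiles_to_graph, tanimoto_similarity
from .errors import EmptySeedError
from .flow import FlowModel
from .head import featurize_latent, unflatten_latent
from .preprocess import ScreeningRecord, filter_record


@dataclass(frozen=True)
class OptimizationConfig:
    """Controls of the latent gradient-descent search."""

    step_sizes: tuple = (0.1, 0.5, 1.0, 2.0)
    steps_per_run: int = 50
    seed_count: int = 140
    similarity_floor: float | None = None
    sas_ceiling: float | None = None
    fp_radius: int = 2
    fp_bits: int = 2048

    def __post_init__(self):
        if not self.step_sizes or any(s <= 0 for s in self.step_sizes):
            raise ValueError("step_sizes must be non-empty and positive")
        if self.steps_per_run < 1:
            raise ValueError("steps_per_run must be >= 1")


@dataclass(frozen=True)
class TrajectoryRecord:
    """One decoded optimization step; ``smiles`` is None on decode failure."""

    step: int
    smiles: str | None
    predicted_gi50: float
    normalized_sas: float | None
    similarity_to_seed: float | None


@dataclass
class GenerationResult:
    """All decoded steps of one (seed, step size) optimization run."""

    seed_smiles: str
    step_size: float
    trajectory: list = field(default_factory=list)


def select_seed_molecules(dataset, k: int):
    """The k most potent (lowest-GI50) dataset entries, ties by SMILES order."""
    if not 1 <= k <= len(dataset):
        raise ValueError(f"k must be in [1, {len(dataset)}]")
    ranked = sorted(dataset.entries, key=lambda e: (e[1], e[0]))
    return [smiles for smiles, _ in ranked[:k]]


def load_clinical_seeds(path):
    """Read a newline-delimited SMILES file, validating each line.

    Returns (seed SMILES list, warnings); every seed has passed the same
    structure filters as the training data.  Raises
    :class:`EmptySeedError` when no line survives.
    """
    seeds, warnings = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            smiles = line.strip()
            if not smiles or smiles.startswith("#"):
                continue
            result = filter_record(ScreeningRecord(0, smiles, "", 0.0))
            if result.kept:
                seeds.append(result.record.smiles)
            else:
                warnings.append(f"line {lineno}: rejected ({result.reason.value}): {smiles}")
    if not seeds:
        raise EmptySeedError(f"no valid seed SMILES in {path}")
    return seeds, warnings


def optimize_latent(seed_graph, model: FlowModel, regressor, step_size: float, steps: int):
    """Deterministic gradient descent from a seed's noise-free encoding.

    Returns the iterates [z_0, ..., z_steps] as LatentPairs; the gradient
    is taken with respect to the flattened latent vector and reshaped.
    """
    if step_size <= 0:
        raise ValueError("step_size must be > 0")
    cfg = model.config
    latent, _, _ = model.encode(seed_graph, rng=None)
    z = featurize_latent(latent)
    iterates = [latent]
    for t in range(steps):
        grad = regressor.gradient(z)
        if not np.isfinite(grad).all():
            raise FloatingPointError(f"non-finite head gradient at step {t + 1}")
        z = z - step_size * grad
        iterates.append(unflatten_latent(z, cfg.dn, cfg.dv, cfg.de))
    return iterates


def run_generation(seeds, model: FlowModel, regressor,
                   config: OptimizationConfig) -> list:
    """Optimize every (seed, step size) pair and score each decoded step.

    Decode failures are recorded in place, never fatal; report-stage
    filters are *not* applied here — the raw trajectory is always kept.
    """
    results = []
    for seed in seeds:
        seed_canonical = Chem.MolToSmiles(Chem.MolFromSmiles(seed))
        seed_graph = smiles_to_graph(seed_canonical, model.atom_vocab,
                                     model.bond_vocab, model.config.dn)
        for eta in config.step_sizes:
            iterates = optimize_latent(seed_graph, model, regressor, eta,
                                       config.steps_per_run)
            result = GenerationResult(seed_smiles=seed_canonical, step_size=float(eta))
            for step, latent in enumerate(iterates):
                if step == 0:
                    smiles, sas, sim = seed_canonical, normalized_sas(seed_canonical), 1.0
                    graph = seed_graph
                else:
                    graph = model.decode(latent)
                    smiles = graph_to_smiles(graph, model.atom_vocab, model.bond_vocab)
                    if smiles is None:
                        sas = sim = None
                    else:
                        sas = normalized_sas(smiles)
                        sim = tanimoto_similarity(seed_canonical, smiles,
                                                  config.fp_radius, config.fp_bits)
                # score the decoded molecule itself (its noise-free encoding);
                # only a failed decode falls back to the free latent point
                if smiles is None:
                    predicted = float(regressor.predict(featurize_latent(latent)))
                else:
                    enc, _, _ = model.encode(graph, rng=None)
                    predicted = float(regressor.predict(featurize_latent(enc)))
                result.trajectory.append(
                    TrajectoryRecord(step, smiles, predicted, sas, sim)
                )
            results.append(result)
    return results


def report_candidates(results, config: OptimizationConfig) -> pd.DataFrame:
    """Ranked candidate table from raw trajectories.

    Deduplicated by canonical SMILES (best = lowest predicted GI50 kept),
    seed molecules themselves excluded, optional SAS-ceiling and
    similarity-floor filters applied, sorted ascending by predicted GI50.
    """
    if not results:
        raise ValueError("results must be non-empty")
    seed_set = {r.seed_smiles for r in results}
    rows = []
    for result in results:
        for rec in result.trajectory:
            if rec.step == 0 or rec.smiles is None or rec.smiles in seed_set:
                continue
            rows.append(
                {
                    "smiles": rec.smiles,
                    "predicted_gi50": rec.predicted_gi50,
                    "normalized_sas": rec.normalized_sas,
                    "similarity": rec.similarity_to_seed,
                    "seed": result.seed_smiles,
                    "step_size": result.step_size,
                    "step": rec.step,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["smiles", "predicted_gi50", "normalized_sas",
                 "similarity", "seed", "step_size", "step"],
    )
    if df.empty:
        return df
    df = df.sort_values(["predicted_gi50", "smiles"], kind="mergesort")
    df = df.drop_duplicates(subset="smiles", keep="first")
    if config.sas_ceiling is not None:
        df = df[df["normalized_sas"] <= config.sas_ceiling]
    if config.similarity_floor is not None:
        df = df[df["similarity"] >= config.similarity_floor]
    return df.reset_index(drop=True)
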