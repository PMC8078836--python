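"""Seeded synthetic datasets with planted, learnable block structure.

The generator partitions diseases and metabolites into co-association blocks:
within-block (disease, metabolite) pairs are associated with an elevated
probability, all other pairs with a low background probability.  Each block
owns a template pathway set and a template symptom set; block members inherit
each template bit with probability ``profile_coherence`` and draw a random bit
otherwise.  This is the minimal structure that makes all three feature
families informative — degree statistics via block density, threshold-graph
communities via coherent profiles, and low-rank factors via the block pattern.

The truth ledger returned alongside the data records block memberships and
the exact expectations of every random draw, so tests can check realised
counts against their sampling distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import AssociationMatrix, PathwayMembership, SymptomCatalog


@dataclass
class GeneratorConfig:
    """Block-model parameters; defaults give a strongly learnable instance."""

    n_diseases: int = 40
    n_metabolites: int = 120
    n_pathways: int = 15
    n_symptoms: int = 25
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.3
    background_assoc_prob: float = 0.01
    profile_coherence: float = 0.9
    template_density: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        if min(self.n_diseases, self.n_metabolites) < self.n_blocks:
            raise ValueError("need at least one disease and metabolite per block")
        for p in (
            self.within_block_assoc_prob,
            self.background_assoc_prob,
            self.profile_coherence,
            self.template_density,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Near-equal contiguous blocks: entity i belongs to block i * n_blocks // n."""
    return (np.arange(n) * n_blocks) // n


def generate(
    config: GeneratorConfig,
) -> tuple[AssociationMatrix, PathwayMembership, SymptomCatalog, dict]:
    """Draw one dataset and its truth ledger from the planted block model."""
    rng = np.random.default_rng(config.seed)
    nd, nm = config.n_diseases, config.n_metabolites
    d_block = _block_assignment(nd, config.n_blocks)
    m_block = _block_assignment(nm, config.n_blocks)
    disease_ids = [f"d{i:04d}" for i in range(nd)]
    metabolite_ids = [f"m{j:04d}" for j in range(nm)]

    within = d_block[:, None] == m_block[None, :]
    prob = np.where(within, config.within_block_assoc_prob, config.background_assoc_prob)
    M = (rng.random((nd, nm)) < prob).astype(float)

    # templates: one random pathway/symptom subset per block
    pathway_templates = rng.random((config.n_blocks, config.n_pathways)) < config.template_density
    symptom_templates = rng.random((config.n_blocks, config.n_symptoms)) < config.template_density

    MP = np.zeros((config.n_pathways, nm))
    for j in range(nm):
        template = pathway_templates[m_block[j]]
        inherit = rng.random(config.n_pathways) < config.profile_coherence
        random_bits = rng.random(config.n_pathways) < config.template_density
        MP[:, j] = np.where(inherit, template, random_bits).astype(float)

    symptoms: dict[str, dict[str, int]] = {}
    for i in range(nd):
        template = symptom_templates[d_block[i]]
        inherit = rng.random(config.n_symptoms) < config.profile_coherence
        random_bits = rng.random(config.n_symptoms) < config.template_density
        present = np.where(inherit, template, random_bits)
        counts = {}
        for s in np.nonzero(present)[0]:
            counts[f"s{s:03d}"] = int(rng.integers(1, 6))
        symptoms[disease_ids[i]] = counts

    n_within = int(within.sum())
    n_between = nd * nm - n_within
    expected_pos = (
        n_within * config.within_block_assoc_prob
        + n_between * config.background_assoc_prob
    )
    var_pos = n_within * config.within_block_assoc_prob * (
        1 - config.within_block_assoc_prob
    ) + n_between * config.background_assoc_prob * (1 - config.background_assoc_prob)
    ledger = {
        "config": asdict(config),
        "disease_blocks": d_block.tolist(),
        "metabolite_blocks": m_block.tolist(),
        "pathway_templates": pathway_templates.astype(int).tolist(),
        "symptom_templates": symptom_templates.astype(int).tolist(),
        "n_within_pairs": n_within,
        "n_between_pairs": n_between,
        "expected_positives": expected_pos,
        "sd_positives": float(np.sqrt(var_pos)),
        "n_positives": int(M.sum()),
        "pathway_membership_colsums": MP.sum(axis=0).tolist(),
        "pathway_membership_rowsums": MP.sum(axis=1).tolist(),
        "symptom_total": int(sum(sum(c.values()) for c in symptoms.values())),
    }
    m = AssociationMatrix(M, disease_ids, metabolite_ids)
    mp = PathwayMembership(MP, [f"p{k:03d}" for k in range(config.n_pathways)], metabolite_ids)
    catalog = SymptomCatalog(symptoms)
    return m, mp, catalog, ledger


def null_config(seed: int = 7) -> GeneratorConfig:
    """A no-signal counterpart: equal within/background rates, zero coherence.

    The association rate is set so the expected positive count matches the
    default planted instance.
    """
    base = GeneratorConfig(seed=seed)
    nd, nm = base.n_diseases, base.n_metabolites
    n_within = int((_block_assignment(nd, base.n_blocks)[:, None]
                    == _block_assignment(nm, base.n_blocks)[None, :]).sum())
    n_total = nd * nm
    rate = (
        n_within * base.within_block_assoc_prob
        + (n_total - n_within) * base.background_assoc_prob
    ) / n_total
    return GeneratorConfig(
        within_block_assoc_prob=rate,
        background_assoc_prob=rate,
        profile_coherence=0.0,
        seed=seed,
    )


def tiny_fixture() -> tuple[AssociationMatrix, PathwayMembership, SymptomCatalog]:
    """Hard-coded 4-disease x 6-metabolite dataset with hand-checkable values."""
    disease_ids = ["d1", "d2", "d3", "d4"]
    metabolite_ids = ["m1", "m2", "m3", "m4", "m5", "m6"]
    M = np.array(
        [
            [1, 1, 0, 0, 0, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [0, 0, 0, 0, 0, 1],
        ],
        dtype=float,
    )
    MP = np.array(
        [
            [1, 1, 0, 0, 1, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 1, 1, 0, 0],
            [0, 0, 0, 1, 1, 1],
        ],
        dtype=float,
    )
    symptoms = {
        "d1": {"s1": 2, "s2": 1},
        "d2": {"s1": 1, "s3": 2},
        "d3": {"s4": 3},
        "d4": {"s2": 1},
    }
    return (
        AssociationMatrix(M, disease_ids, metabolite_ids),
        PathwayMembership(MP, ["p1", "p2", "p3", "p4"], metabolite_ids),
        SymptomCatalog(symptoms),
    )


def write_dataset(
    m: AssociationMatrix,
    mp: PathwayMembership,
    catalog: SymptomCatalog,
    outdir: str | Path,
    ledger: dict | None = None,
) -> dict[str, Path]:
    """Write the three input TSVs (plus optional ledger JSON) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "pathways": outdir / "pathways.tsv",
        "symptoms": outdir / "symptoms.tsv",
    }
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        for d, met in sorted(m.pairs()):
            fh.write(f"{d}\t{met}\n")
    with open(paths["pathways"], "w", encoding="utf-8") as fh:
        pi, mj = np.nonzero(mp.MP)
        rows = sorted((mp.metabolite_ids[j], mp.pathway_ids[i]) for i, j in zip(pi, mj))
        for met, p in rows:
            fh.write(f"{met}\t{p}\n")
    with open(paths["symptoms"], "w", encoding="utf-8") as fh:
        for d in sorted(catalog.symptoms):
            for s, n in sorted(catalog.symptoms[d].items()):
                fh.write(f"{d}\t{s}\t{n}\n")
    if ledger is not None:
        paths["ledger"] = outdir / "truth_ledger.json"
        paths["ledger"].write_text(json.dumps(ledger, indent=2), encoding="utf-8")
    return paths
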