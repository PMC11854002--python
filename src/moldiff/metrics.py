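"""Evaluation metrics for generated molecule sets.

Molecule identity is canonical-SMILES equality throughout.  Novelty is the
fraction of generated molecules (as a multiset) whose canonical form does not
occur in the training set; uniqueness the fraction of distinct canonical
SMILES among the generated ones; internal diversity one minus the mean
pairwise Tanimoto similarity of 2048-bit Morgan fingerprints of radius 2
(IntDiv with power 1), with a singleton set scored 0 by convention.
Property-distribution reports add per-property summaries and, given a
reference set, the two-sample Kolmogorov–Smirnov distance per property.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .codec import canonical_smiles
from .properties import PROPERTY_NAMES, property_table

__all__ = ["novelty", "uniqueness", "internal_diversity",
           "property_distribution_report", "generation_report"]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _canon(smiles_list: list[str]) -> list[str]:
    return [canonical_smiles(s) for s in smiles_list]


def novelty(generated: list[str], training: list[str]) -> float:
    """Fraction of generated molecules absent from the training set."""
    if not generated:
        raise ValueError("empty generated set")
    train = set(_canon(training))
    gen = _canon(generated)
    return sum(1 for s in gen if s not in train) / len(gen)


def uniqueness(generated: list[str]) -> float:
    """Fraction of distinct canonical SMILES among the generated molecules."""
    if not generated:
        raise ValueError("empty generated set")
    gen = _canon(generated)
    return len(set(gen)) / len(gen)


def internal_diversity(generated: list[str]) -> float:
    """1 - mean pairwise (i != j) Morgan-Tanimoto similarity; singleton -> 0."""
    if not generated:
        raise ValueError("empty generated set")
    mols = [Chem.MolFromSmiles(s) for s in generated]
    if any(m is None for m in mols):
        raise ValueError("internal_diversity requires valid molecules")
    if len(mols) == 1:
        return 0.0
    fps = [_MORGAN.GetFingerprint(m) for m in mols]
    n = len(fps)
    total = 0.0
    for i in range(n - 1):
        total += sum(DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:]))
    mean_sim = 2.0 * total / (n * (n - 1))
    return 1.0 - mean_sim


def property_distribution_report(generated: list[str],
                                 properties: list[str] | None = None,
                                 reference: list[str] | None = None) -> pd.DataFrame:
    """Per-property mean/sd/quantiles, plus KS distance to a reference set."""
    if not generated:
        raise ValueError("empty generated set")
    properties = list(properties) if properties else list(PROPERTY_NAMES)
    table = property_table(generated)[properties]
    rows = {}
    ref_table = property_table(reference)[properties] if reference else None
    for prop in properties:
        x = table[prop].to_numpy()
        row = {"mean": x.mean(), "sd": x.std(ddof=0),
               "q25": np.quantile(x, 0.25), "median": np.quantile(x, 0.5),
               "q75": np.quantile(x, 0.75)}
        if ref_table is not None:
            row["ks_distance"] = float(stats.ks_2samp(x, ref_table[prop].to_numpy()).statistic)
        rows[prop] = row
    return pd.DataFrame(rows).T


def generation_report(generated: list[str], training: list[str],
                      properties: list[str] | None = None) -> dict:
    """Combined scores + property summaries, JSON-serialisable."""
    return {
        "n_generated": len(generated),
        "novelty": novelty(generated, training),
        "uniqueness": uniqueness(generated),
        "internal_diversity": internal_diversity(generated),
        "properties": property_distribution_report(generated, properties)
        .to_dict(orient="index"),
    }
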