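"""Experiment orchestration: guidance-strength sweeps, multi-property
scenarios, fingerprint PCA, and the drug-likeness filter.

A :class:`ModelBundle` collects the trained components one run needs (VAE,
denoiser + schedule, property predictors).  ``guidance_sweep`` generates a
molecule set per guidance strength under a shared seed — so the zero-strength
condition is exactly the unguided sampler — and tabulates the ground-truth
property distribution of each set.  ``multi_property_run`` executes several
multi-term guidance scenarios and projects the pooled molecules onto the
first two principal components of their 166-bit MACCS structural-key
fingerprints, the standard low-dimensional view of chemical-space separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, QED
from sklearn.decomposition import PCA

from .codec import Vocabulary, write_molecule_file
from .ddpm import Denoiser, NoiseSchedule
from .guidance import GuidanceSpec, sample_guided
from .properties import PredictorHandle, compute_properties
from .vae import VAE

__all__ = ["ModelBundle", "guidance_sweep", "multi_property_run",
           "maccs_pca", "drug_likeness_filter"]


@dataclass
class ModelBundle:
    """Everything a generation experiment needs, trained and ready."""

    vae: VAE
    denoiser: Denoiser
    schedule: NoiseSchedule
    predictors: dict[str, PredictorHandle] = field(default_factory=dict)

    @property
    def vocab(self) -> Vocabulary:
        return self.vae.vocab


def guidance_sweep(property_name: str, strengths: list[float], n: int,
                   seed: int, bundle: ModelBundle,
                   out_dir: str | Path | None = None
                   ) -> tuple[pd.DataFrame, dict[float, list[str]]]:
    """Generate ``n`` molecules per guidance strength and tabulate the target
    property.

    Strengths must be distinct and include 0 (the unguided reference).  All
    conditions share the same seed, so they are paired: the zero-strength row
    is exactly unguided generation and differences across rows are due to
    guidance alone.  Returns the summary table and the per-strength molecule
    sets; molecule files are written when ``out_dir`` is given.
    """
    if len(set(strengths)) != len(strengths):
        raise ValueError("strengths must be distinct")
    if 0.0 not in strengths:
        raise ValueError("strengths must include 0 (unguided reference)")
    if property_name not in bundle.predictors:
        raise KeyError(f"no trained predictor for {property_name!r}")
    predictor = bundle.predictors[property_name]

    rows = []
    molecules: dict[float, list[str]] = {}
    for s in strengths:
        spec = GuidanceSpec(terms=((predictor, float(s)),))
        smiles = sample_guided(n, spec, bundle.schedule, bundle.denoiser,
                               bundle.vae, seed=seed)
        molecules[s] = smiles
        # empty-molecule sentinels carry no properties
        values = np.array([compute_properties(smi)[property_name]
                           for smi in smiles if smi])
        rows.append({"strength": s, "n": n, "n_valid": len(values),
                     "mean": values.mean(), "sd": values.std(ddof=1),
                     "sem": values.std(ddof=1) / np.sqrt(len(values)),
                     "q25": np.quantile(values, 0.25),
                     "median": np.quantile(values, 0.5),
                     "q75": np.quantile(values, 0.75)})
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_molecule_file(smiles, out_dir / f"{property_name}_s{s:+g}.smi")
    table = pd.DataFrame(rows).sort_values("strength").reset_index(drop=True)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / f"{property_name}_sweep.csv", index=False)
    return table, molecules


def maccs_pca(smiles_by_label: dict[str, list[str]]) -> pd.DataFrame:
    """Joint 2-component PCA on MACCS fingerprints of labelled molecule sets.

    Component signs follow a fixed convention — the largest-magnitude loading
    of each component is made positive — so coordinates are deterministic.
    """
    labels, fps = [], []
    for label, smiles in smiles_by_label.items():
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumAtoms() == 0:
                continue
            fps.append(np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64))
            labels.append(label)
    X = np.stack(fps)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(2):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1.0
    return pd.DataFrame({"label": labels, "pc1": coords[:, 0], "pc2": coords[:, 1]})


def multi_property_run(scenarios: dict[str, GuidanceSpec], n: int, seed: int,
                       bundle: ModelBundle, out_dir: str | Path | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Run several multi-term guidance scenarios under a shared seed.

    Returns (scenario summary with logP / heavy-atom centroids, MACCS-PCA
    coordinates of the pooled molecules labelled by scenario, molecule sets).
    """
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios")
    if n < 1:
        raise ValueError("n must be >= 1")
    molecules: dict[str, list[str]] = {}
    rows = []
    for label, spec in scenarios.items():
        smiles = sample_guided(n, spec, bundle.schedule, bundle.denoiser,
                               bundle.vae, seed=seed)
        molecules[label] = smiles
        props = [compute_properties(s) for s in smiles if s]
        logp = np.array([p["logP"] for p in props])
        heavy = np.array([p["n_heavy_atoms"] for p in props])
        rows.append({"scenario": label, "n": n,
                     "logP_mean": logp.mean(), "logP_sd": logp.std(ddof=1),
                     "heavy_atoms_mean": heavy.mean(),
                     "heavy_atoms_sd": heavy.std(ddof=1)})
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_molecule_file(smiles, out / f"scenario_{label}.smi")
    table = pd.DataFrame(rows)
    pca_coords = maccs_pca(molecules)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "scenarios.csv", index=False)
        pca_coords.to_csv(Path(out_dir) / "scenarios_pca.csv", index=False)
    return table, pca_coords, molecules


def drug_likeness_filter(smiles_list: list[str]) -> list[str]:
    """Keep drug-like molecules: QED >= 0.6 and no rings with <4 or >6 atoms."""
    kept = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        sizes = [len(r) for r in mol.GetRingInfo().AtomRings()]
        if any(s < 4 or s > 6 for s in sizes):
            continue
        if QED.qed(mol) < 0.6:
            continue
        kept.append(smi)
    return kept
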