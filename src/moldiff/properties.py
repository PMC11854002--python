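"""Molecular property calculators and differentiable surrogate predictors.

Two kinds of property machinery live here:

* ground-truth calculators built on RDKit descriptors (logP, QED, TPSA, the
  Ertl–Schuffenhauer synthetic-accessibility score, ring statistics, …) and
  the penalised logP, ``p_logP = logP - SA - n_largerings`` where a "large
  ring" has more than 6 atoms;
* trained surrogate predictors: small MLP regressors over flattened one-hot
  token matrices.  They accept relaxed (probability-row) encodings and are
  differentiable with respect to their input, which is the contract the
  guidance mechanism relies on — gradients of a predicted property can be
  backpropagated through the VAE decoder onto the latent space.

Labels are z-scored internally during surrogate training and un-scaled at
prediction time, so guidance gradients have comparable magnitude across
properties with very different natural ranges.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, QED, RDConfig, rdMolDescriptors
from scipy import stats

from . import _nn
from .codec import CodecError, MoleculeRecord, Vocabulary, to_onehot

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

__all__ = [
    "PROPERTY_NAMES",
    "compute_properties",
    "penalized_logp",
    "property_table",
    "PredictorConfig",
    "PredictorHandle",
    "LatentLinearPredictor",
    "train_predictor",
    "predict",
    "read_label_csv",
]

PROPERTY_NAMES = (
    "logP", "QED", "SA", "molecular_weight", "molar_refractivity", "TPSA",
    "n_rotatable_bonds", "n_hbd", "n_hba", "n_atoms", "n_heavy_atoms",
    "formal_charge", "n_rings", "n_small_or_large_cycles", "p_logP",
)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    return mol


def _n_large_rings(mol: Chem.Mol) -> int:
    """Rings with more than 6 atoms (the penalised-logP penalty term)."""
    return sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > 6)


def compute_properties(smiles: str) -> dict[str, float]:
    """All supported descriptors for one molecule, keyed by PROPERTY_NAMES."""
    mol = _mol(smiles)
    ring_sizes = [len(r) for r in mol.GetRingInfo().AtomRings()]
    logp = Descriptors.MolLogP(mol)
    sa = sascorer.calculateScore(mol) if mol.GetNumAtoms() else 0.0
    return {
        "logP": logp,
        "QED": QED.qed(mol),
        "SA": sa,
        "molecular_weight": Descriptors.MolWt(mol),
        "molar_refractivity": Descriptors.MolMR(mol),
        "TPSA": Descriptors.TPSA(mol),
        "n_rotatable_bonds": float(Descriptors.NumRotatableBonds(mol)),
        "n_hbd": float(Descriptors.NumHDonors(mol)),
        "n_hba": float(Descriptors.NumHAcceptors(mol)),
        "n_atoms": float(Chem.AddHs(mol).GetNumAtoms()),
        "n_heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "formal_charge": float(Chem.GetFormalCharge(mol)),
        "n_rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "n_small_or_large_cycles": float(sum(1 for s in ring_sizes if s <= 4 or s >= 7)),
        "p_logP": logp - sa - _n_large_rings(mol),
    }


def penalized_logp(smiles: str) -> float:
    """logP penalised by synthetic accessibility and large (>6-atom) rings."""
    mol = _mol(smiles)
    return (Descriptors.MolLogP(mol) - sascorer.calculateScore(mol)
            - _n_large_rings(mol))


def property_table(smiles_list: list[str]) -> pd.DataFrame:
    """Property matrix for a molecule set (rows aligned with the input)."""
    return pd.DataFrame([compute_properties(s) for s in smiles_list],
                        index=pd.Index(smiles_list, name="smiles"))


# ---------------------------------------------------------------------------
# surrogate predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorConfig:
    hidden_dims: tuple[int, ...] = (128, 64)
    epochs: int = 120
    batch_size: int = 64
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.1
    seed: int = 0


@dataclass
class PredictorHandle:
    """A trained differentiable property surrogate.

    ``model`` maps a flattened one-hot matrix to a z-scored prediction;
    ``label_mean``/``label_std`` restore the natural property scale.
    ``holdout_r`` is the Pearson correlation between prediction and label on
    the held-out split, the predictor-quality figure reported after training.
    """

    name: str
    model: _nn.MLP
    input_shape: tuple[int, int]
    label_mean: float
    label_std: float
    holdout_r: float
    latent_space: bool = False

    def predict_tensor(self, probs: _nn.Tensor) -> _nn.Tensor:
        """Z-scored prediction for a batch tensor (n, max_len * |V|)."""
        n = probs.shape[0]
        flat = probs.reshape(n, self.input_shape[0] * self.input_shape[1])
        return self.model(flat).reshape(n)


class LatentLinearPredictor:
    """Toy predictor y(z) = w . z acting directly on latent vectors.

    Used as an analytic oracle for the guidance update: the induced one-step
    shift has a closed form, so tests can compare the implementation against
    algebra instead of against itself.
    """

    latent_space = True

    def __init__(self, w: np.ndarray, name: str = "linear_latent"):
        self.w = np.asarray(w, dtype=np.float64)
        self.name = name

    def predict_tensor(self, z: _nn.Tensor) -> _nn.Tensor:
        return (z * self.w).sum(axis=1)


def read_label_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a smiles,value label table; every row must carry a finite value."""
    df = pd.read_csv(path)
    for col in ("smiles", "value"):
        if col not in df.columns:
            raise CodecError(f"{path}: label CSV missing required '{col}' column")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=np.float64)))
    if bad.size:
        raise CodecError(f"{path}: missing/non-numeric value in row {bad[0] + 2} "
                         f"(smiles={df['smiles'].iloc[bad[0]]!r})")
    return [str(s) for s in df["smiles"]], values.to_numpy(dtype=np.float64)


def train_predictor(records: list[MoleculeRecord], vocab: Vocabulary,
                    labels: np.ndarray | str,
                    config: PredictorConfig = PredictorConfig(),
                    name: str | None = None) -> PredictorHandle:
    """Fit an MLP surrogate of a property on one-hot encodings.

    ``labels`` is either an array (one finite value per record, e.g. from an
    external assay/docking table) or a property name from PROPERTY_NAMES, in
    which case labels are computed with the ground-truth calculator.
    """
    if isinstance(labels, str):
        name = name or labels
        labels = np.array([compute_properties(r.smiles)[name] for r in records])
    labels = np.asarray(labels, dtype=np.float64)
    name = name or "property"
    if len(labels) != len(records):
        raise CodecError(f"{len(records)} molecules but {len(labels)} labels")
    if not np.all(np.isfinite(labels)):
        raise CodecError("labels must be finite")

    mu, sd = float(labels.mean()), float(labels.std())
    if sd == 0.0:
        warnings.warn(f"labels for {name!r} are constant; Pearson r is undefined "
                      "and the predictor will return the constant")
        sd = 1.0
    y = (labels - mu) / sd

    X = np.stack([to_onehot(r, vocab).ravel() for r in records])
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(X))
    n_hold = max(1, int(round(config.holdout_fraction * len(X)))) if len(X) > 2 else 0
    hold, train = perm[:n_hold], perm[n_hold:]

    model = _nn.MLP([X.shape[1], *config.hidden_dims, 1], rng)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    n_train = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = train[order[start:start + config.batch_size]]
            xb = _nn.Tensor(X[idx])
            pred = model(xb).reshape(len(idx))
            err = pred - _nn.Tensor(y[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()

    if n_hold >= 2:
        pred_hold = model(_nn.Tensor(X[hold])).data.ravel()
        if np.std(pred_hold) == 0 or np.std(y[hold]) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(pred_hold, y[hold])[0])
    else:
        r = float("nan")
    return PredictorHandle(name=name, model=model,
                           input_shape=(vocab.max_len, len(vocab)),
                           label_mean=mu, label_std=sd, holdout_r=r)


def save_predictor(handle: PredictorHandle, path: str | Path) -> None:
    import json
    dims = [handle.model.layers[0].W.data.shape[0]] + \
           [layer.W.data.shape[1] for layer in handle.model.layers]
    arrays = {f"p{i}": a for i, a in enumerate(handle.model.state_arrays())}
    np.savez(path, _meta=json.dumps({
        "name": handle.name, "dims": dims, "input_shape": list(handle.input_shape),
        "label_mean": handle.label_mean, "label_std": handle.label_std,
        "holdout_r": handle.holdout_r}), **arrays)


def load_predictor(path: str | Path) -> PredictorHandle:
    import json
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["_meta"]))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    model = _nn.MLP(meta["dims"], np.random.default_rng(0))
    model.load_state_arrays(arrays)
    return PredictorHandle(name=meta["name"], model=model,
                           input_shape=tuple(meta["input_shape"]),
                           label_mean=meta["label_mean"], label_std=meta["label_std"],
                           holdout_r=meta["holdout_r"])


def predict(handle: PredictorHandle, encoding: np.ndarray) -> float:
    """Predicted property value (natural scale) for one one-hot matrix."""
    enc = np.asarray(encoding, dtype=np.float64)
    if enc.shape != handle.input_shape:
        raise CodecError(f"encoding shape {enc.shape} does not match predictor "
                         f"input {handle.input_shape}")
    z = handle.predict_tensor(_nn.Tensor(enc.reshape(1, -1)))
    return float(z.data[0] * handle.label_std + handle.label_mean)
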