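"""Glue between raw profiles, pair lists and the estimator stack."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from .dvm import DVMClassifier
from .pssm import EvolutionMatrix, ScoreMatrix, evolution_matrix, parse_pssm
from .twodpca import TwoDPCA

__all__ = [
    "evolution_matrices",
    "load_pssm_dir",
    "pair_stack",
    "make_pipeline",
    "pair_feature_table",
    "split_feature_table",
]


def load_pssm_dir(pssm_dir: str | Path, ids) -> dict[str, ScoreMatrix]:
    """Load ``<id>.pssm`` files for the given protein ids.

    Raises FileNotFoundError naming the first missing protein id.
    """
    pssm_dir = Path(pssm_dir)
    out = {}
    for pid in ids:
        path = pssm_dir / f"{pid}.pssm"
        if not path.exists():
            raise FileNotFoundError(f"no PSSM file for protein id {pid!r}: {path}")
        out[pid] = parse_pssm(path.read_text(), protein_id=pid)
    return out


def evolution_matrices(
    proteins, normalize: str = "none"
) -> dict[str, EvolutionMatrix]:
    """Per-protein 20 x 20 evolution matrices, keyed by protein id."""
    items = proteins.values() if isinstance(proteins, dict) else proteins
    return {p.protein_id: evolution_matrix(p, normalize=normalize) for p in items}


def pair_stack(
    matrices: dict[str, EvolutionMatrix], pairs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair samples into X of shape (n, 2, 20, 20) and labels y."""
    missing = (set(pairs["id_a"]) | set(pairs["id_b"])) - set(matrices)
    if missing:
        raise KeyError(f"pairs reference unknown protein ids: {sorted(missing)[:5]}")
    X = np.stack(
        [
            np.stack([matrices[a].values, matrices[b].values])
            for a, b in zip(pairs["id_a"], pairs["id_b"])
        ]
    )
    y = pairs["label"].to_numpy(dtype=int)
    return X, y


def make_pipeline(d: int = 3, **dvm_params) -> Pipeline:
    """2DPCA featurisation followed by the DVM classifier.

    Fitting the pipeline fits the projection basis on the training pairs'
    proteins only, so cross-validation over the pipeline is leakage-free.
    """
    return Pipeline(
        [
            ("twodpca", TwoDPCA(n_components=d)),
            ("dvm", DVMClassifier(**dvm_params)),
        ]
    )


def pair_feature_table(
    matrices: dict[str, EvolutionMatrix],
    pairs: pd.DataFrame,
    d: int = 3,
) -> tuple[pd.DataFrame, TwoDPCA]:
    """Fitted pair-feature table (basis from all listed proteins).

    Returns a DataFrame with columns ``id_a``, ``id_b``, ``label``,
    ``f1..f{40d}`` plus the fitted transformer.  Intended for exploratory /
    export use; for honest cross-validation prefer :func:`make_pipeline`,
    which refits the basis per training fold.
    """
    X, y = pair_stack(matrices, pairs)
    tx = TwoDPCA(n_components=d).fit(X)
    feats = tx.transform(X)
    feat_frame = pd.DataFrame(
        feats, columns=[f"f{j + 1}" for j in range(feats.shape[1])],
        index=pairs.index,
    )
    table = pd.concat([pairs[["id_a", "id_b", "label"]], feat_frame], axis=1)
    return table, tx


def split_feature_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a pair-feature table written by this package."""
    feat_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    if not feat_cols:
        raise ValueError("no feature columns f1..fN found in table")
    feat_cols.sort(key=lambda c: int(c[1:]))
    return table[feat_cols].to_numpy(dtype=float), table["label"].to_numpy(dtype=int)
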