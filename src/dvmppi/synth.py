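"""Synthetic PSSM and protein-pair dataset generation.

Real inputs to the pipeline are PSI-BLAST profiles of proteins from curated
interaction databases, which cannot be redistributed or recomputed offline.
This module emulates their *shape*: integer L x 20 log-odds matrices whose
column means carry a class signal.  Injecting signal at the column-mean level
is the generative assumption that makes the downstream pipeline testable —
column-mean shifts survive the M'M transpose-product and the 2DPCA
projection, so separation in template space translates into separation in the
120-dim pair-feature space.  No claim of biological realism is made: real
profiles have position-dependent structure, composition biases and
inter-column correlations that this generator does not model.

Protein "classes" are two template groups; interacting pairs are drawn within
a group and non-interacting pairs across groups.  With ``separation=0`` the
two templates coincide and the labels are independent of the features (a null
dataset); with separation well above the noise scale the classes become
linearly separable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pssm import AMINO_ACIDS, ScoreMatrix

__all__ = ["SynthConfig", "synth_pssm", "synth_pair_dataset", "write_dataset"]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic pair dataset.

    Defaults give 40 proteins of realistic post-filter lengths (50-120
    residues), 200 interacting + 200 non-interacting pairs, log-odds noise
    sd 2.0 around the templates and integer clipping to the typical
    PSI-BLAST span -10..12.  ``separation`` is the between-template mean
    shift per PSSM column, in log-odds units; 12 (six noise sd) gives
    clearly separable classes, 0 gives a label-free null.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (50, 120)
    n_pos: int = 200
    n_neg: int = 200
    separation: float = 12.0
    noise_sd: float = 2.0
    score_range: tuple[int, int] = (-10, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if self.length_range[0] < 1:
            raise ValueError("minimum length must be >= 1")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n_pos + self.n_neg == 0:
            raise ValueError("need at least one pair")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def synth_pssm(
    protein_id: str,
    length: int,
    class_template: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    score_range: tuple[int, int] = (-10, 12),
) -> ScoreMatrix:
    """One synthetic L x 20 PSSM around a 20-vector of column-mean log-odds.

    scores[i, a] = round(template[a] + N(0, noise_sd)), clipped to
    ``score_range``; residues are drawn uniformly from the 20 letters.
    """
    template = np.asarray(class_template, dtype=float)
    if template.shape != (20,):
        raise ValueError("class_template must be a 20-vector")
    raw = template + rng.normal(0.0, noise_sd, size=(length, 20))
    scores = np.clip(np.round(raw), *score_range).astype(np.int64)
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ScoreMatrix(protein_id=protein_id, scores=scores, residues=residues)


def _templates(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    base = rng.uniform(-2.0, 2.0, size=20)
    signs = rng.choice([-1.0, 1.0], size=20)
    return base - signs * cfg.separation / 2.0, base + signs * cfg.separation / 2.0


def synth_pair_dataset(
    cfg: SynthConfig,
) -> tuple[list[ScoreMatrix], pd.DataFrame]:
    """Generate proteins and a labeled pair list under ``cfg``.

    Proteins split evenly between the two template groups.  Interacting
    pairs (label 1) are drawn within a group, non-interacting pairs (label 0)
    across groups.  Deterministic under ``cfg.seed``.

    Returns
    -------
    (proteins, pairs)
        ``proteins`` is a list of :class:`ScoreMatrix`; ``pairs`` a DataFrame
        with columns ``id_a``, ``id_b``, ``label``.
    """
    rng = np.random.default_rng(cfg.seed)
    t0, t1 = _templates(cfg, rng)
    half = cfg.n_proteins // 2
    groups = [0] * half + [1] * (cfg.n_proteins - half)
    proteins = []
    for i, g in enumerate(groups):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        proteins.append(
            synth_pssm(
                f"P{i:04d}",
                length,
                t0 if g == 0 else t1,
                cfg.noise_sd,
                rng,
                cfg.score_range,
            )
        )
    ids = np.array([p.protein_id for p in proteins])
    groups = np.asarray(groups)
    rows = []
    for _ in range(cfg.n_pos):  # within-group pairs
        g = int(rng.integers(0, 2))
        a, b = rng.choice(np.where(groups == g)[0], size=2, replace=True)
        rows.append((ids[a], ids[b], 1))
    for _ in range(cfg.n_neg):  # cross-group pairs
        a = rng.choice(np.where(groups == 0)[0])
        b = rng.choice(np.where(groups == 1)[0])
        if rng.integers(0, 2):
            a, b = b, a
        rows.append((ids[a], ids[b], 0))
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "label"])
    if cfg.separation == 0:
        # templates coincide, but group membership would still leak protein
        # identity; shuffling the labels makes this a true null dataset
        pairs["label"] = rng.permutation(pairs["label"].to_numpy())
    return proteins, pairs


def write_dataset(
    proteins: list[ScoreMatrix],
    pairs: pd.DataFrame,
    out_dir: str | Path,
    cfg: SynthConfig | None = None,
) -> None:
    """Write PSSM files, the pair-list TSV and a manifest JSON to a directory."""
    from .pssm import write_pssm

    out = Path(out_dir)
    pssm_dir = out / "pssm"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    for p in proteins:
        (pssm_dir / f"{p.protein_id}.pssm").write_text(write_pssm(p))
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    if cfg is not None:
        (out / "manifest.json").write_text(json.dumps(asdict(cfg), indent=2))
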