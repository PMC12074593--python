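"""Per-residue feature matrices.

Two providers share one contract (L rows, finite entries):

* ``plm-adapter`` — a protein-language-model adapter producing the real
  D=2560 per-residue embeddings (final-layer residue representations).
  It requires the optional ``esm`` backend plus its weights and is never
  needed by the test suite.
* ``synthetic`` — a deterministic Gaussian provider used throughout the
  tests, optionally planting a class signal of controllable effect size
  along a fixed unit direction.

Computed embeddings can be cached to disk keyed by a sequence hash, so the
expensive model runs at most once per sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from graphbind.errors import ProviderError, ShapeError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PLM_DIM = 2560


@dataclass(frozen=True)
class FeatureMatrix:
    """An L x D real matrix of per-residue features."""

    values: np.ndarray
    provider_tag: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ShapeError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ProviderConfig:
    """Which provider to use and how.

    ``dim`` is 2560 for the plm-adapter; free for the synthetic provider.
    ``class_shift`` (synthetic only) is the effect size: labeled-positive rows
    are shifted by ``class_shift`` along a fixed seeded unit direction.
    """

    provider: str = "synthetic"
    dim: int = 32
    seed: int = 0
    class_shift: float = 0.0
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.provider not in ("plm-adapter", "synthetic"):
            raise ValueError(f"unknown provider {self.provider!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AA_ALPHABET) - {"X"}
    if bad:
        raise ValueError(f"non-standard residue codes {sorted(bad)}; only the 20 "
                         "standard letters plus X are accepted")


def _seq_rng(seq: str, seed: int) -> np.random.Generator:
    """RNG that is a pure function of (sequence, seed)."""
    digest = hashlib.sha256(f"{seed}:{seq}".encode()).digest()
    return np.random.default_rng(np.frombuffer(digest[:16], dtype=np.uint64))


def _cache_path(cache_dir: str, seq: str, cfg: ProviderConfig) -> Path:
    key = hashlib.sha256(f"{cfg.provider}:{cfg.dim}:{cfg.seed}:{seq}".encode()).hexdigest()[:24]
    return Path(cache_dir) / f"{key}.npy"


def embed_sequence(seq: str, cfg: ProviderConfig | None = None) -> FeatureMatrix:
    """Embed an amino-acid sequence into an L x D feature matrix.

    The synthetic provider is deterministic in (seq, cfg.seed) and carries no
    class information (class signal is planted only by
    :func:`synthetic_features_for_labels`, which knows the labels).
    """
    cfg = cfg or ProviderConfig()
    _validate_sequence(seq)
    if cfg.cache_dir:
        path = _cache_path(cfg.cache_dir, seq, cfg)
        if path.exists():
            return FeatureMatrix(np.load(path), provider_tag=cfg.provider)
    if cfg.provider == "plm-adapter":
        values = _plm_embed(seq)
    else:
        values = _seq_rng(seq, cfg.seed).standard_normal((len(seq), cfg.dim))
    if cfg.cache_dir:
        path = _cache_path(cfg.cache_dir, seq, cfg)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path, values)
    return FeatureMatrix(values, provider_tag=cfg.provider)


def _plm_embed(seq: str) -> np.ndarray:
    """Final-layer per-residue representations from the 3B-parameter ESM2 model."""
    try:
        import esm  # type: ignore[import-not-found]
        import torch  # type: ignore[import-not-found]
    except ImportError as exc:
        raise ProviderError(
            "the plm-adapter provider needs the 'fair-esm' and 'torch' packages "
            "plus the esm2_t36_3B_UR50D weights; install them or switch to "
            "provider='synthetic'"
        ) from exc
    model, alphabet = esm.pretrained.esm2_t36_3B_UR50D()
    model.eval()
    batch_converter = alphabet.get_batch_converter()
    _, _, tokens = batch_converter([("query", seq)])
    with torch.no_grad():
        out = model(tokens, repr_layers=[model.num_layers])
    rep = out["representations"][model.num_layers][0, 1:len(seq) + 1]
    return rep.cpu().numpy().astype(float)


def embed_fasta(path: str | Path, cfg: ProviderConfig | None = None) -> dict[str, FeatureMatrix]:
    """Embed every record of a FASTA file; returns {record-id: matrix}."""
    out: dict[str, FeatureMatrix] = {}
    name, chunks = None, []
    lines = list(Path(path).read_text().splitlines()) + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None:
                out[name] = embed_sequence("".join(chunks), cfg)
            name, chunks = line[1:].split()[0] if line[1:].strip() else None, []
        else:
            chunks.append(line.strip())
    return out


def synthetic_features_for_labels(
    labels: np.ndarray, cfg: ProviderConfig | None = None
) -> FeatureMatrix:
    """Gaussian features with a planted class signal.

    Row i is standard normal noise plus ``class_shift * mu`` when
    ``labels[i] == 1``, where ``mu`` is a fixed unit direction drawn once from
    ``cfg.seed``. With class_shift d the two classes are unit-variance
    Gaussians separated by d along mu, so the Bayes error of the oracle
    projection is Phi(-d/2).
    """
    cfg = cfg or ProviderConfig()
    if cfg.provider != "synthetic":
        raise ValueError("synthetic_features_for_labels requires provider='synthetic'")
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be a flat 0/1 vector")
    rng = np.random.default_rng(cfg.seed)
    mu = rng.standard_normal(cfg.dim)
    mu /= np.linalg.norm(mu)
    values = rng.standard_normal((len(labels), cfg.dim))
    values[labels == 1] += cfg.class_shift * mu
    return FeatureMatrix(values, provider_tag="synthetic")


def class_direction(cfg: ProviderConfig) -> np.ndarray:
    """The unit direction along which the synthetic class signal is planted."""
    rng = np.random.default_rng(cfg.seed)
    mu = rng.standard_normal(cfg.dim)
    return mu / np.linalg.norm(mu)
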