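"""Synthetic genetic-interaction profiles with planted functional modules.

Real inputs to this package are Pearson-correlation similarity matrices
between per-gene genetic-interaction profiles (vectors of epistasis-like
scores against a common query panel). This module emulates that pipeline
statistically: genes belong to modules, each module carries a latent signal,
and every gene's profile is a noisy copy of its module's signal. Correlating
the simulated profiles then yields a similarity matrix with positive blocks
on the diagonal (within-module pairs) and weak or negative similarity
between blocks — the structure the downstream balance analyses probe.

Calibration uses the one-factor construction

    x_i = sqrt(rho_w) * g_m(i) + sqrt(1 - rho_w) * noise_sd * z_i

with unit-variance module signals g_m and i.i.d. standard-normal noise z_i,
so that at ``noise_sd = 1`` the expected Pearson correlation of a
same-module pair is exactly ``rho_w = within_module_corr``. Negative
between-module targets are produced by anti-correlating the module signals
themselves: Corr(g_a, g_b) = between_module_corr / within_module_corr for
a != b, which makes the expected cross-module profile correlation equal to
``between_module_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SimilarityMatrix

__all__ = [
    "ProfileModel",
    "ProfileMatrix",
    "ParameterError",
    "DegenerateProfileError",
    "generate_profiles",
    "profiles_to_similarity",
    "write_profiles",
]


class ParameterError(ValueError):
    """A generator parameter violates a model invariant."""


class DegenerateProfileError(ValueError):
    """A profile has zero variance, so its Pearson correlation is undefined."""


@dataclass(frozen=True)
class ProfileModel:
    """Parameters of the planted-module profile generator.

    Parameters
    ----------
    n_genes:
        Number of genes (rows of the profile matrix).
    n_modules:
        Number of planted functional modules; genes are split into
        near-equal contiguous blocks.
    profile_length:
        Number of query genes per profile (columns); the Pearson-correlation
        sampling noise scales as ``1/sqrt(profile_length)``.
    within_module_corr:
        Target expected correlation of same-module gene pairs, in [0, 1).
    between_module_corr:
        Target expected correlation of cross-module pairs, in (-1, 0].
    noise_sd:
        Standard deviation multiplier of the idiosyncratic noise term.
        At 1.0 the within/between targets are hit exactly in expectation;
        0.0 makes same-module profiles identical copies of the signal.
    seed:
        Mandatory RNG seed; the output is deterministic given the seed.
    """

    n_genes: int
    n_modules: int = 1
    profile_length: int = 500
    within_module_corr: float = 0.5
    between_module_corr: float = -0.15
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be a positive integer")
        if not 1 <= self.n_modules <= self.n_genes:
            raise ParameterError("need 1 <= n_modules <= n_genes")
        if self.profile_length < 3:
            raise ParameterError("profile_length must be >= 3 (Pearson correlation needs >= 3 points)")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ParameterError("within_module_corr must lie in [0, 1)")
        if not -1.0 < self.between_module_corr <= 0.0:
            raise ParameterError("between_module_corr must lie in (-1, 0]")
        if self.within_module_corr <= self.between_module_corr:
            raise ParameterError("within_module_corr must exceed between_module_corr")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.n_modules > 1 and self.within_module_corr > 0:
            # Module-signal correlation matrix must stay positive semidefinite.
            c = self.between_module_corr / self.within_module_corr
            if c < -1.0 / (self.n_modules - 1) - 1e-12:
                raise ParameterError(
                    "between_module_corr too negative: requires "
                    f"between/within >= -1/(n_modules-1) = {-1.0 / (self.n_modules - 1):.4f}"
                )


@dataclass(frozen=True)
class ProfileMatrix:
    """Simulated gene-by-query interaction-score matrix."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    module_assignment: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape[0] != len(self.gene_ids):
            raise ParameterError("row count must equal number of gene_ids")
        if np.isnan(values).any():
            raise ParameterError("profile matrix contains missing values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "module_assignment", np.asarray(self.module_assignment, dtype=int))


def _module_signals(model: ProfileModel, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance module signals with pairwise correlation between/within."""
    m, L = model.n_modules, model.profile_length
    raw = rng.standard_normal((m, L))
    if m == 1 or model.within_module_corr == 0.0:
        return raw
    c = model.between_module_corr / model.within_module_corr
    corr = np.full((m, m), c)
    np.fill_diagonal(corr, 1.0)
    # Cholesky with a tiny jitter at the PSD boundary c = -1/(m-1).
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    return chol @ raw


def generate_profiles(model: ProfileModel) -> ProfileMatrix:
    """Simulate per-gene interaction profiles under the planted-module model.

    Deterministic given ``model.seed``: two calls with equal models return
    bit-identical matrices.
    """
    rng = np.random.default_rng(model.seed)
    assignment = np.sort(np.arange(model.n_genes) % model.n_modules)
    signals = _module_signals(model, rng)
    rho = model.within_module_corr
    noise = rng.standard_normal((model.n_genes, model.profile_length))
    values = np.sqrt(rho) * signals[assignment] + np.sqrt(1.0 - rho) * model.noise_sd * noise
    gene_ids = tuple(f"G{i:04d}" for i in range(model.n_genes))
    return ProfileMatrix(values=values, gene_ids=gene_ids, module_assignment=assignment)


def profiles_to_similarity(profiles: ProfileMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation of profiles, diagonal forced to zero.

    Raises
    ------
    DegenerateProfileError
        If any profile is constant (zero variance), naming the genes.
    """
    values = profiles.values
    if values.shape[1] < 3:
        raise DegenerateProfileError("profiles need >= 3 points for Pearson correlation")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [profiles.gene_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise DegenerateProfileError(f"constant profiles (zero variance): {bad}")
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return SimilarityMatrix(values=corr, gene_ids=profiles.gene_ids)


def write_profiles(profiles: ProfileMatrix, path: str | Path) -> None:
    """Write the profile matrix as a labeled TSV (genes x queries)."""
    df = pd.DataFrame(
        profiles.values,
        index=list(profiles.gene_ids),
        columns=[f"Q{j:04d}" for j in range(profiles.values.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")
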