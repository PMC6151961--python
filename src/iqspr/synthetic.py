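"""Synthetic descriptor/property data with a known latent structure.

Every modelling stage is testable without external descriptor software: the
generator plants a low-rank latent structure

    X_informative = T·P_trueᵀ + E,   Y = T·C_trueᵀ + F,   T ~ N(0, I)

among a larger block of pure-noise descriptors, converts a few informative
columns to binary by median thresholding (so subset selection can plausibly
pick binary descriptors, as real Dragon blocks contain), and labels the two
responses (logkw, logKi). Defaults mirror the scale of a small sulphonamide
QSPR study: 45 compounds, a few hundred descriptors, 4 latent dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DescriptorTable, PropertyTable, ReferenceProperties, ValidationError


@dataclass
class SyntheticSpec:
    n_compounds: int = 45
    n_descriptors: int = 300
    latent_dim: int = 4
    n_informative: int = 20
    n_binary: int = 3
    noise_sd_x: float = 0.3
    noise_sd_y: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValidationError("n_informative exceeds n_descriptors")
        if self.latent_dim > self.n_informative:
            raise ValidationError("latent_dim exceeds n_informative")
        if self.n_binary > self.n_informative:
            raise ValidationError("n_binary exceeds n_informative")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.n_compounds < 3:
            raise ValidationError("need at least 3 compounds")


@dataclass
class SyntheticTruth:
    P_true: np.ndarray            # (n_informative, latent_dim)
    C_true: np.ndarray            # (2, latent_dim)
    informative_names: list[str]
    scores: np.ndarray            # (n, latent_dim)
    Y_clean: np.ndarray           # (n, 2)
    spec: SyntheticSpec = field(repr=False, default=None)


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, PropertyTable, SyntheticTruth]:
    """Seeded draw of (descriptors, properties, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n, p, L = spec.n_compounds, spec.n_descriptors, spec.latent_dim
    ninf = spec.n_informative
    T = rng.standard_normal((n, L))
    # orthonormal latent directions over the informative block: a
    # well-conditioned planted structure, so the informative descriptors are
    # jointly identifiable (no accidental near-collinearity of the truth)
    P_true, _ = np.linalg.qr(rng.standard_normal((ninf, L)))
    # every latent factor feeds the property block with unit strength; when
    # the latent dimension fits inside the two-response space the directions
    # are taken orthogonal, so the factors stay separately identifiable from
    # the properties (with more factors than responses that is impossible and
    # random unit directions are used)
    if L <= 2:
        C_true = np.linalg.qr(rng.standard_normal((2, 2)))[0][:, :L]
    else:
        C_true = rng.standard_normal((2, L))
        C_true /= np.linalg.norm(C_true, axis=0, keepdims=True)
    X = rng.standard_normal((n, p))            # uninformative: pure noise
    X[:, :ninf] = T @ P_true.T * np.sqrt(ninf / L) + spec.noise_sd_x * rng.standard_normal((n, ninf))
    # binary descriptors: threshold latent-driven columns at their median
    for j in range(spec.n_binary):
        X[:, j] = (X[:, j] > np.median(X[:, j])).astype(float)
    Y_clean = T @ C_true.T
    Y = Y_clean + spec.noise_sd_y * rng.standard_normal((n, 2))
    width = max(3, len(str(p)))
    names = [f"D{j + 1:0{width}d}" for j in range(p)]
    ids = [f"S{i + 1:03d}" for i in range(n)]
    kinds = ["binary" if j < spec.n_binary else "continuous" for j in range(p)]
    desc = DescriptorTable(ids, names, X, kinds)
    props = PropertyTable(ids, Y[:, 0], Y[:, 1])
    truth = SyntheticTruth(P_true=P_true, C_true=C_true,
                           informative_names=names[:ninf], scores=T,
                           Y_clean=Y_clean, spec=spec)
    return desc, props, truth


def make_reference(truth: SyntheticTruth, compound_index: int,
                   desc: DescriptorTable) -> tuple[ReferenceProperties, np.ndarray]:
    """Noiseless properties + descriptor row of one compound.

    Mirrors the use of a known potent, lipophilic ligand as the inversion
    reference: the returned properties are the clean (noise-free) responses,
    the descriptor vector is the compound's row for round-trip checks.
    """
    if not 0 <= compound_index < truth.scores.shape[0]:
        raise ValidationError(f"compound index {compound_index} out of range")
    y = truth.Y_clean[compound_index]
    ref = ReferenceProperties(logkw_ref=float(y[0]), logKi_ref=float(y[1]))
    return ref, desc.values[compound_index].copy()
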