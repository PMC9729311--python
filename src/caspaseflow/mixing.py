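"""Linear spectral unmixing of four-band fluorescence into fluorophore abundances.

A :class:`MixingModel` holds the channels × fluorophores emission weight
matrix that describes how each fluorophore leaks into each detection band.
Observed channel intensities are ``M @ a`` for abundance vector ``a``;
unmixing inverts this per frame (ordinary or nonnegative least squares).

Columns are stored normalized to unit sum. Any fixed normalization suffices:
all downstream quantities are ratios of abundances or are normalized to
initial values, so the per-fluorophore scale convention cancels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .containers import AbundanceTraceSet, ChannelTraceSet

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_FLUOROPHORES",
    "MixingModel",
    "build_mixing_model",
    "default_mixing_model",
    "identity_mixing_model",
    "unmix",
    "unmix_traces",
    "unmix_stack",
]

#: Detection bands of the four-photomultiplier setup (nm).
DEFAULT_CHANNELS = ("460-510", "520-550", "575-620", "655-755")

#: Donor/acceptor fluorophores of the two cleavable probes, in channel order.
DEFAULT_FLUOROPHORES = ("GFP", "Alexa532", "RFP", "Alexa660")

# Plausible placeholder leakage weights (rows = channels, cols = fluorophores).
# SYNTHETIC: not calibrated against measured emission spectra, which are only
# published graphically; diagonal-dominant with short-wavelength tails.
_DEFAULT_WEIGHTS = np.array(
    [
        # GFP   A532   RFP    A660
        [0.85, 0.08, 0.00, 0.00],
        [0.12, 0.80, 0.08, 0.02],
        [0.03, 0.10, 0.80, 0.08],
        [0.00, 0.02, 0.12, 0.90],
    ]
)


@dataclass(frozen=True)
class MixingModel:
    """Column-normalized fluorophore-by-channel emission weight matrix."""

    channels: tuple
    fluorophores: tuple
    weights: np.ndarray  # shape (n_channels, n_fluorophores), columns sum to 1
    condition_number: float
    ill_conditioned: bool

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_fluorophores(self) -> int:
        return len(self.fluorophores)

    def to_json(self, path) -> None:
        payload = {
            "channels": list(self.channels),
            "fluorophores": list(self.fluorophores),
            "weights": self.weights.tolist(),  # row-major, channels x fluorophores
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "MixingModel":
        payload = json.loads(Path(path).read_text())
        return build_mixing_model(
            np.asarray(payload["weights"], dtype=float),
            channel_labels=tuple(payload["channels"]),
            fluorophore_labels=tuple(payload["fluorophores"]),
        )


def build_mixing_model(
    reference_weights,
    channel_labels=DEFAULT_CHANNELS,
    fluorophore_labels=DEFAULT_FLUOROPHORES,
    condition_threshold: float = 1e6,
) -> MixingModel:
    """Validate and column-normalize reference emission weights.

    Raises on negative weights, all-zero columns and rank-deficient matrices;
    warns (and flags the model) when the condition number exceeds
    ``condition_threshold``.
    """
    w = np.array(reference_weights, dtype=float)
    if w.ndim != 2 or w.shape != (len(channel_labels), len(fluorophore_labels)):
        raise ValueError(
            f"weights shape {w.shape} does not match "
            f"{len(channel_labels)} channels x {len(fluorophore_labels)} fluorophores"
        )
    if np.any(w < 0):
        raise ValueError("mixing weights must be nonnegative")
    colsums = w.sum(axis=0)
    if np.any(colsums <= 0):
        bad = [fluorophore_labels[i] for i in np.flatnonzero(colsums <= 0)]
        raise ValueError(f"all-zero emission column(s) for: {bad}")
    w = w / colsums
    if np.linalg.matrix_rank(w) < min(w.shape):
        raise ValueError("singular mixing matrix: fluorophore spectra are linearly dependent")
    cond = float(np.linalg.cond(w))
    ill = cond > condition_threshold
    if ill:
        warnings.warn(
            f"mixing matrix condition number {cond:.3g} exceeds {condition_threshold:.3g}; "
            "ols unmixing will refuse this model",
            stacklevel=2,
        )
    return MixingModel(
        channels=tuple(channel_labels),
        fluorophores=tuple(fluorophore_labels),
        weights=w,
        condition_number=cond,
        ill_conditioned=ill,
    )


def default_mixing_model() -> MixingModel:
    """Four-band model with plausible (non-calibrated) cross-talk weights."""
    return build_mixing_model(_DEFAULT_WEIGHTS)


def identity_mixing_model() -> MixingModel:
    """Leakage-free model: each fluorophore emits only into its own band."""
    return build_mixing_model(np.eye(4))


def _solve_ols(weights: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Least-squares abundances for observations of shape (n, n_channels)."""
    if weights.shape[0] == weights.shape[1]:
        return np.linalg.solve(weights, obs.T).T
    sol, *_ = np.linalg.lstsq(weights, obs.T, rcond=None)
    return sol.T


def unmix(observations, model: MixingModel, mode: str = "ols"):
    """Invert channel intensities to fluorophore abundances, frame by frame.

    Parameters
    ----------
    observations
        Array of shape ``(n_frames, n_channels)`` (a single frame vector is
        also accepted).
    model
        The mixing model; its channel count must match the observations.
    mode
        ``"ols"`` (ordinary least squares, the default) or ``"nnls"``
        (abundances constrained nonnegative).

    Returns
    -------
    abundances : ndarray, shape (n_frames, n_fluorophores)
    residuals : ndarray, shape (n_frames,)
        Euclidean norm of ``model @ a - observed`` per frame.
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.shape[1] != model.n_channels:
        raise ValueError(
            f"observations have {obs.shape[1]} channels, model has {model.n_channels}"
        )
    if mode == "ols":
        if model.ill_conditioned:
            raise ValueError(
                f"mixing model is ill-conditioned (condition number "
                f"{model.condition_number:.3g}); use nnls mode or fix the model"
            )
        a = _solve_ols(model.weights, obs)
    elif mode == "nnls":
        a = np.empty((obs.shape[0], model.n_fluorophores))
        for i, row in enumerate(obs):
            a[i], _ = nnls(model.weights, row)
    else:
        raise ValueError(f"unknown unmixing mode {mode!r}")
    resid = np.linalg.norm(obs - a @ model.weights.T, axis=1)
    return a, resid


def unmix_traces(traces: ChannelTraceSet, model: MixingModel, mode: str = "ols") -> AbundanceTraceSet:
    """Apply :func:`unmix` to every cell of a channel trace set."""
    n_cells, _, n_frames = traces.data.shape
    data = np.empty((n_cells, model.n_fluorophores, n_frames))
    residuals = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        a, r = unmix(traces.data[i].T, model, mode=mode)
        data[i] = a.T
        residuals[i] = r
    return AbundanceTraceSet(
        cell_ids=list(traces.cell_ids),
        labels=model.fluorophores,
        frame_interval=traces.frame_interval,
        data=data,
        residuals=residuals,
    )


def unmix_stack(stack: np.ndarray, model: MixingModel, mode: str = "ols"):
    """Pixel-wise unmixing of a ``(T, C, Y, X)`` image stack.

    Returns an abundance stack ``(T, F, Y, X)`` and residual norms
    ``(T, Y, X)``. In ols mode this commutes with ROI averaging (unmixing is
    linear), so per-pixel and ROI-mean pipelines agree.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must have shape (T, C, Y, X)")
    t, c, y, x = stack.shape
    if c != model.n_channels:
        raise ValueError(f"stack has {c} channels, model has {model.n_channels}")
    obs = stack.transpose(0, 2, 3, 1).reshape(-1, c)
    a, resid = unmix(obs, model, mode=mode)
    abundance = a.reshape(t, y, x, model.n_fluorophores).transpose(0, 3, 1, 2)
    return abundance, resid.reshape(t, y, x)
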