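"""Spectral diagnostics for the enhancement operator.

The diffusion is, in exact arithmetic, a pure spectral filter: it keeps the
eigenvectors of the localized doubly stochastic operator and pushes each
eigenvalue through the shrinkage map. These utilities certify that behavior
on concrete matrices — eigenvalue images, eigengap growth, connected-component
counts, and worst-case eigenvector drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import subspace_angles

from .enhance import LocalizedDSM, map_eigenvalue
from .network import ValidationError

__all__ = ["SpectralReport", "spectral_report", "eigengap"]

#: eigenvalues closer than this are treated as one degenerate cluster
DEGENERACY_TOL = 1e-6
#: multiplicity of eigenvalue 1 counted within this tolerance
COMPONENT_TOL = 1e-8


@dataclass
class SpectralReport:
    """Before/after spectra of a diffusion step.

    Eigenvalues are sorted descending; ``eigengaps_*[i]`` is
    ``lam_{i+1} - lam_{i+2}`` in 1-based terms (index 1 = top gap).
    ``component_count`` is the multiplicity of eigenvalue 1 of the operator,
    i.e. the number of connected components. ``max_eigenvector_drift`` is the
    worst ``1 - |cos angle|`` between matched invariant subspaces: degenerate
    eigenvalue clusters are compared via principal angles because individual
    eigenvectors inside a cluster are not identifiable.
    ``max_map_deviation`` is the largest gap between the eigenvalues of the
    diffused matrix and the shrinkage-map images of the operator's.
    """

    eigenvalues_before: np.ndarray
    eigenvalues_after: np.ndarray
    eigengaps_before: np.ndarray
    eigengaps_after: np.ndarray
    component_count: int
    max_eigenvector_drift: float
    max_map_deviation: float


def eigengap(matrix: np.ndarray, index: int) -> float:
    """Gap ``lam_index - lam_{index+1}`` of the descending-sorted spectrum.

    ``index`` is 1-based from the top: ``index=1`` is the gap below the
    leading eigenvalue.
    """
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if not 1 <= index < n:
        raise ValidationError(f"eigengap index must lie in [1, {n - 1}], got {index}")
    lam = np.sort(np.linalg.eigvalsh(M))[::-1]
    return float(lam[index - 1] - lam[index])


def spectral_report(T: LocalizedDSM, W_star: np.ndarray, alpha: float) -> SpectralReport:
    """Compare the spectrum of the operator with that of its diffused image."""
    op = T.operator
    W = np.asarray(W_star, dtype=float)
    if W.shape != op.shape:
        raise ValidationError(f"shape mismatch: {op.shape} vs {W.shape}")

    lam_T, V_T = np.linalg.eigh(op)
    lam_W, V_W = np.linalg.eigh(W)
    # descending order
    lam_T, V_T = lam_T[::-1], V_T[:, ::-1]
    lam_W, V_W = lam_W[::-1], V_W[:, ::-1]

    mapped = map_eigenvalue(np.clip(lam_T, -1.0, 1.0), alpha)
    max_dev = float(np.abs(np.sort(lam_W) - np.sort(mapped)).max())

    drift = _max_subspace_drift(lam_T, V_T, V_W)

    return SpectralReport(
        eigenvalues_before=lam_T,
        eigenvalues_after=lam_W,
        eigengaps_before=-np.diff(lam_T),
        eigengaps_after=-np.diff(lam_W),
        component_count=int(np.sum(lam_T >= 1.0 - COMPONENT_TOL)),
        max_eigenvector_drift=drift,
        max_map_deviation=max_dev,
    )


def _max_subspace_drift(lam: np.ndarray, V_before: np.ndarray, V_after: np.ndarray) -> float:
    """Worst 1 - cos(principal angle) across eigenvalue clusters.

    The shrinkage map is strictly increasing on [0, 1], so sorted positions
    match before and after; eigenvalues closer than DEGENERACY_TOL form one
    cluster whose invariant subspaces are compared as wholes.
    """
    n = lam.size
    clusters: list[list[int]] = [[0]]
    for i in range(1, n):
        if lam[i - 1] - lam[i] < DEGENERACY_TOL:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    worst = 0.0
    for idx in clusters:
        A = V_before[:, idx]
        B = V_after[:, idx]
        angles = subspace_angles(A, B)
        worst = max(worst, float(1.0 - np.cos(angles).min()))
    return worst
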