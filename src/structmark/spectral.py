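"""Eigenvalue-based structural descriptors.

The default battery has eleven measures: four on the adjacency spectrum
(graph energy, Estrada index, spectral radius, spectral gap), four on the
distance spectrum (distance energy, distance Estrada index, distance
spectral radius, smallest distance eigenvalue) and three on the Laplacian
spectrum (Laplacian energy, Laplacian Estrada index, algebraic
connectivity). Spectra come from a symmetric eigensolver, never from
characteristic-polynomial root finding.

Estrada-type sums are evaluated in log-sum-exp form; when the exponent
exceeds ~700 the natural value would overflow a double, so the log-domain
value is reported instead and the measure name is flagged in
``SpectralDescriptorSet.log_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .graph_core import GraphMatrices

__all__ = [
    "MatrixKind",
    "Spectrum",
    "SpectralDescriptorSet",
    "SPECTRAL_DESCRIPTOR_NAMES",
    "spectrum",
    "spectral_descriptors",
    "sign_ratio",
]

_EXP_OVERFLOW = 700.0  # exp() overflows float64 slightly above 709


class MatrixKind(str, Enum):
    adjacency = "adjacency"
    distance = "distance"
    laplacian = "laplacian"


@dataclass(frozen=True)
class Spectrum:
    """Real eigenvalues of a symmetric graph matrix, non-increasing."""

    matrix_kind: MatrixKind
    eigenvalues: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


#: Stable column order of the default eleven-measure battery.
SPECTRAL_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "energy",
    "estrada_index",
    "spectral_radius",
    "spectral_gap",
    "distance_energy",
    "distance_estrada_index",
    "distance_spectral_radius",
    "distance_min_eigenvalue",
    "laplacian_energy",
    "laplacian_estrada_index",
    "algebraic_connectivity",
)


@dataclass(frozen=True)
class SpectralDescriptorSet:
    """Named descriptor values plus the set of log-domain-flagged names."""

    values: dict[str, float]
    log_scale: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite descriptor {name}={v}")


def spectrum(mats: GraphMatrices, kind: MatrixKind | str) -> Spectrum:
    """Full real spectrum of the requested matrix, sorted non-increasing."""
    kind = MatrixKind(kind)
    mat = {
        MatrixKind.adjacency: mats.adjacency,
        MatrixKind.distance: mats.distance,
        MatrixKind.laplacian: mats.laplacian,
    }[kind]
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{kind.value} matrix is not symmetric")
    eigs = np.linalg.eigvalsh(mat)[::-1]
    return Spectrum(matrix_kind=kind, eigenvalues=tuple(float(x) for x in eigs))


def _estrada(eigs: np.ndarray) -> tuple[float, bool]:
    """Sum of exp(eigenvalues) via log-sum-exp; (value, log_domain_flag)."""
    log_val = float(logsumexp(eigs))
    if log_val > _EXP_OVERFLOW:
        return log_val, True
    return float(np.exp(log_val)), False


def spectral_descriptors(mats: GraphMatrices) -> SpectralDescriptorSet:
    """Compute the default eleven-measure battery for one graph.

    Distance-based measures use ``mats.distance`` (largest component for
    disconnected graphs); adjacency and Laplacian measures use the full
    graph.
    """
    a_eigs = np.asarray(spectrum(mats, MatrixKind.adjacency).eigenvalues)
    d_eigs = np.asarray(spectrum(mats, MatrixKind.distance).eigenvalues)
    l_eigs = np.asarray(spectrum(mats, MatrixKind.laplacian).eigenvalues)
    n, m = mats.n, mats.m

    values: dict[str, float] = {}
    flags: set[str] = set()

    values["energy"] = float(np.abs(a_eigs).sum())
    est, flag = _estrada(a_eigs)
    values["estrada_index"] = est
    if flag:
        flags.add("estrada_index")
    values["spectral_radius"] = float(a_eigs[0])
    values["spectral_gap"] = float(a_eigs[0] - a_eigs[1]) if n > 1 else 0.0

    values["distance_energy"] = float(np.abs(d_eigs).sum())
    est, flag = _estrada(d_eigs)
    values["distance_estrada_index"] = est
    if flag:
        flags.add("distance_estrada_index")
    values["distance_spectral_radius"] = float(d_eigs[0])
    values["distance_min_eigenvalue"] = float(d_eigs[-1])

    mean_degree = 2.0 * m / n
    values["laplacian_energy"] = float(np.abs(l_eigs - mean_degree).sum())
    est, flag = _estrada(l_eigs)
    values["laplacian_estrada_index"] = est
    if flag:
        flags.add("laplacian_estrada_index")
    # second-smallest Laplacian eigenvalue; 0 for disconnected graphs
    values["algebraic_connectivity"] = float(l_eigs[-2]) if n > 1 else 0.0

    return SpectralDescriptorSet(values=values, log_scale=frozenset(flags))


def sign_ratio(
    spec: Spectrum, zero_tol: float = 1e-9
) -> tuple[float, float]:
    """(fraction negative, fraction positive) over eigenvalues with
    magnitude above *zero_tol*."""
    if zero_tol < 0:
        raise ValueError("zero_tol must be non-negative")
    eigs = np.asarray(spec.eigenvalues)
    nonzero = eigs[np.abs(eigs) > zero_tol]
    if nonzero.size == 0:
        raise ValueError("all eigenvalues are within zero_tol of zero")
    neg = float((nonzero < 0).sum()) / nonzero.size
    pos = float((nonzero > 0).sum()) / nonzero.size
    return neg, pos
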