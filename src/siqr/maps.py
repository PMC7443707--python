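"""Voxelwise functional-coefficient maps and eigenfunction volumes.

The score-space slopes of a fitted quantile model correspond to a functional
coefficient ``beta_tau(t) = sum_m b_m,tau psi_m(t)`` on the voxel grid; a red
voxel (positive value) means local expansion there increases predicted brain
age at that quantile.  Because the basis inner product is the unit-weight
voxel cross product, the plug-in prediction ``alpha + sum_t X_c(t) beta(t)``
(voxel sum of the centred smooth image times the map) equals the score-space
prediction exactly — the identity tying all pipeline stages together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .basis import BasisSystem
from .fpca import EigenSystem
from .quantreg import QuantileModel
from .volumes import SmoothMask, Volume3D, mask_embed, read_volume, write_volume

__all__ = ["CoefficientMap", "reconstruct_beta", "export_volume"]


@dataclass(frozen=True)
class CoefficientMap:
    """Functional regression coefficient rendered on the voxel grid.

    Units: years of predicted age per unit image intensity per voxel of the
    (unit-weight) integration sum.  Identically zero outside the mask.
    """

    tau: float
    volume: Volume3D


def reconstruct_beta(
    model: QuantileModel,
    eigen: EigenSystem,
    basis: BasisSystem,
    mask: SmoothMask,
) -> CoefficientMap:
    """Render beta_tau = sum_m b_m xi_m expanded through the basis."""
    if model.M > eigen.M_max:
        raise ValueError("model uses more components than the eigensystem has")
    coef = eigen.xi[:, : model.M] @ model.b_hat
    values = basis.design @ coef
    return CoefficientMap(tau=model.tau, volume=mask_embed(values, mask))


def eigenfunction_volume(
    eigen: EigenSystem, index: int, basis: BasisSystem, mask: SmoothMask
) -> Volume3D:
    """Render one eigenfunction on the voxel grid (zero outside the mask)."""
    values = basis.design @ eigen.xi[:, index]
    return mask_embed(values, mask)


def export_volume(
    volume: Volume3D | CoefficientMap,
    path: str | Path,
    reference: Volume3D | SmoothMask | None = None,
) -> Path:
    """Write a map or eigenfunction volume to NIfTI, checking geometry.

    Re-reading the file yields an identical array (float64 round-trip).
    """
    vol = volume.volume if isinstance(volume, CoefficientMap) else volume
    if reference is not None:
        ref_shape = reference.shape
        ref_vs = reference.voxel_size_mm
        if vol.shape != ref_shape or not np.allclose(
            vol.voxel_size_mm, ref_vs
        ):
            raise ValueError(
                f"geometry mismatch: {vol.shape}/{vol.voxel_size_mm} vs "
                f"reference {ref_shape}/{ref_vs}"
            )
    return write_volume(vol, path)
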