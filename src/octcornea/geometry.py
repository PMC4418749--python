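"""Physical calibration of the B-scan raster.

The depth axis of a spectral-domain OCT raster stores *optical path
length*: a layer of geometric thickness ``t`` and group refractive index
``n`` spans ``n * t`` micrometres of optical path.  All depth-pixel
coordinates in this package are optical-path pixels; geometric
thicknesses are recovered by dividing optical distances by the corneal
group index (1.376 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import GeometryError

#: Corneal group refractive index used to convert optical path to
#: geometric thickness.
CORNEAL_GROUP_INDEX = 1.376


@dataclass(frozen=True)
class OpticalGeometry:
    """Raster size and physical extents of one B-scan.

    Parameters
    ----------
    depth_px, width_px
        Raster size (rows = depth samples, columns = A-scans).
    depth_extent_mm
        Optical-path depth span covered by ``depth_px`` rows.
    width_extent_mm
        Lateral span covered by ``width_px`` A-scans.
    axial_psf_fwhm_um
        Full width at half maximum of the axial point-spread function,
        in optical-path micrometres (the instrument's axial resolution
        in tissue).
    group_index
        Group refractive index of the imaged tissue.
    """

    depth_px: int = 1365
    width_px: int = 2048
    depth_extent_mm: float = 2.01
    width_extent_mm: float = 8.41
    axial_psf_fwhm_um: float = 3.0
    group_index: float = CORNEAL_GROUP_INDEX

    def __post_init__(self):
        if self.depth_px <= 0 or self.width_px <= 0:
            raise GeometryError("raster dimensions must be positive")
        if self.depth_extent_mm <= 0 or self.width_extent_mm <= 0:
            raise GeometryError("physical extents must be positive")
        if self.axial_psf_fwhm_um <= 0:
            raise GeometryError("axial PSF FWHM must be positive")
        if self.group_index < 1:
            raise GeometryError("group index must be >= 1")

    @property
    def axial_pitch_um(self) -> float:
        """Optical-path micrometres per depth pixel (~1.4725 by default)."""
        return self.depth_extent_mm * 1000.0 / self.depth_px

    @property
    def lateral_pitch_um(self) -> float:
        """Micrometres per A-scan column (~4.106 by default)."""
        return self.width_extent_mm * 1000.0 / self.width_px

    @property
    def axial_psf_sigma_px(self) -> float:
        """Gaussian sigma of the axial PSF in depth pixels."""
        fwhm_px = self.axial_psf_fwhm_um / self.axial_pitch_um
        return fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    # --- unit conversions -------------------------------------------------
    def optical_px_to_geometric_um(self, delta_px: float) -> float:
        """Convert an optical-path pixel separation to geometric um."""
        return delta_px * self.axial_pitch_um / self.group_index

    def geometric_um_to_optical_px(self, um: float) -> float:
        """Convert a geometric thickness in um to optical-path pixels."""
        return um * self.group_index / self.axial_pitch_um

    def geometric_um_to_optical_um(self, um: float) -> float:
        return um * self.group_index
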