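"""Image-quality metrics: CNR, relative CNR, HU accuracy, HU uniformity.

CNR of an insert against the phantom background is

    CNR_i = (HU_i - HU_bkg) / sqrt((sigma_i^2 + sigma_bkg^2) / 2)

with ROI means and population standard deviations.  rCNR is the per-insert
ratio of a test image's CNR to a reference image's; HU accuracy compares ROI
means to the theoretical HU of each insert material; HU uniformity is the
central-ROI mean minus the mean of four peripheral-ROI means (a cupping /
beam-hardening indicator).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .phantom import ROI, ROISet, theoretical_hu
from .reconstruction import Volume


@dataclass(frozen=True)
class ROIStats:
    mean_hu: float
    sd_hu: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValidationError("ROI must contain at least one voxel")
        if self.sd_hu < 0:
            raise ValidationError("standard deviation cannot be negative")


def roi_stats(volume: Volume, roi: ROI, iz: int = 0) -> ROIStats:
    """Mean and population SD over voxels whose centres lie in the ROI disk."""
    if volume.unit != "hu":
        raise ValidationError("ROI statistics require an HU volume")
    plane = volume.plane(iz)
    x, y = volume.grid.pixel_centers()
    mask = (x - roi.cx) ** 2 + (y - roi.cy) ** 2 <= roi.radius**2
    if not np.any(mask):
        raise DegenerateInputError(f"ROI {roi.name} contains no voxel centres")
    vals = plane[mask]
    return ROIStats(
        mean_hu=float(vals.mean()), sd_hu=float(vals.std()), voxel_count=int(vals.size)
    )


def cnr(insert: ROIStats, background: ROIStats) -> float:
    denom = np.sqrt((insert.sd_hu**2 + background.sd_hu**2) / 2.0)
    if denom == 0:
        raise DegenerateInputError("both ROIs are exactly uniform; CNR undefined")
    return (insert.mean_hu - background.mean_hu) / denom


def rcnr(cnr_vmi, cnr_reference):
    """Per-insert CNR ratios and their mean +/- sd (zero references excluded)."""
    cnr_vmi = np.asarray(cnr_vmi, float)
    cnr_reference = np.asarray(cnr_reference, float)
    if cnr_vmi.shape != cnr_reference.shape:
        raise ValidationError("CNR lists must be paired")
    valid = cnr_reference != 0
    if not np.all(valid):
        warnings.warn("insert(s) with zero reference CNR excluded from mean rCNR")
    ratios = np.full(cnr_vmi.shape, np.nan)
    ratios[valid] = cnr_vmi[valid] / cnr_reference[valid]
    kept = ratios[valid]
    return ratios, float(kept.mean()), float(kept.std())


def hu_accuracy(volume: Volume, roiset: ROISet, energy: float, iz: int = 0):
    """Per-insert Delta-HU = measured mean - theoretical, plus mean +/- sd."""
    deltas = {}
    for roi in roiset.insert_rois:
        if roi.material is None:
            raise ValidationError(f"ROI {roi.name} has no material for HU accuracy")
        stats = roi_stats(volume, roi, iz)
        deltas[roi.name] = stats.mean_hu - theoretical_hu(roi.material, energy)
    vals = np.array(list(deltas.values()))
    return deltas, float(vals.mean()), float(vals.std())


def hu_uniformity(volume: Volume, uniformity_rois, iz: int = 0) -> float:
    """Centre-ROI mean minus the mean of the four peripheral-ROI means."""
    if len(uniformity_rois) != 5:
        raise ValidationError("uniformity needs exactly 1 centre + 4 peripheral ROIs")
    center, *periph = uniformity_rois
    center_mean = roi_stats(volume, center, iz).mean_hu
    periph_means = [roi_stats(volume, r, iz).mean_hu for r in periph]
    return float(center_mean - np.mean(periph_means))


@dataclass(frozen=True)
class MetricsReport:
    energy: float
    insert_names: tuple
    cnr_vmi: tuple
    cnr_reference: tuple
    rcnr_per_insert: tuple
    rcnr_mean: float
    rcnr_sd: float
    delta_hu: dict
    delta_hu_mean: float
    delta_hu_sd: float
    uniformity_hu: float | None
    uniformity_reference_hu: float | None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for k, name in enumerate(self.insert_names):
            rows.append(
                dict(
                    insert=name,
                    cnr_vmi=self.cnr_vmi[k],
                    cnr_reference=self.cnr_reference[k],
                    rcnr=self.rcnr_per_insert[k],
                    delta_hu=self.delta_hu[name],
                )
            )
        rows.append(
            dict(
                insert="summary_mean",
                cnr_vmi=np.mean(self.cnr_vmi),
                cnr_reference=np.mean(self.cnr_reference),
                rcnr=self.rcnr_mean,
                delta_hu=self.delta_hu_mean,
            )
        )
        pd.DataFrame(rows).to_csv(path, index=False)


def build_report(
    vmi_volume: Volume,
    reference_volume: Volume,
    roiset: ROISet,
    energy: float,
    uniformity_volume: Volume | None = None,
    uniformity_reference: Volume | None = None,
    provenance: dict | None = None,
) -> MetricsReport:
    """Assemble rCNR / HU-accuracy / uniformity metrics for one VMI."""
    if vmi_volume.grid != reference_volume.grid:
        raise ValidationError("VMI and reference must share one grid")
    bkg_v = roi_stats(vmi_volume, roiset.background_roi)
    bkg_r = roi_stats(reference_volume, roiset.background_roi)
    names, cv, cr = [], [], []
    for roi in roiset.insert_rois:
        names.append(roi.name)
        cv.append(cnr(roi_stats(vmi_volume, roi), bkg_v))
        cr.append(cnr(roi_stats(reference_volume, roi), bkg_r))
    ratios, r_mean, r_sd = rcnr(cv, cr)
    deltas, d_mean, d_sd = hu_accuracy(vmi_volume, roiset, energy)
    unif = unif_ref = None
    if uniformity_volume is not None:
        unif = hu_uniformity(uniformity_volume, roiset.uniformity_rois)
    if uniformity_reference is not None:
        unif_ref = hu_uniformity(uniformity_reference, roiset.uniformity_rois)
    return MetricsReport(
        energy=float(energy),
        insert_names=tuple(names),
        cnr_vmi=tuple(cv),
        cnr_reference=tuple(cr),
        rcnr_per_insert=tuple(ratios),
        rcnr_mean=r_mean,
        rcnr_sd=r_sd,
        delta_hu=deltas,
        delta_hu_mean=d_mean,
        delta_hu_sd=d_sd,
        uniformity_hu=unif,
        uniformity_reference_hu=unif_ref,
        provenance=provenance or {},
    )
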