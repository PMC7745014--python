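"""Z-scaled network maps, artifact flagging, and component selection.

Each spatial source is scaled to unit standard deviation over the mask
(a "Z map") and displayed above a one-sided cutoff (Z > 2.5 by default).
Components are flagged as artifacts by quantitative proxies of the usual
visual criteria: a map whose suprathreshold voxels hug the rim of the
brain mask (``edge_dominated``) or fall mostly outside a gray-matter
reference mask (``outside_gm``).  Which of the surviving components enter
the statistics is configuration (an explicit id list and/or an ROI-overlap
rule), never inferred anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .errors import ConfigError, DegenerateSourceError, DimensionMismatchError


@dataclass
class ZMap:
    """A source map in unit-SD units with a one-sided display threshold."""

    component_id: int
    zvalues: np.ndarray  # (V,) over mask voxels, SD = 1
    threshold: float = 2.5

    @property
    def thresholded(self) -> np.ndarray:
        """Copy with all voxels <= threshold zeroed (one-sided)."""
        out = self.zvalues.copy()
        out[out <= self.threshold] = 0.0
        return out

    @property
    def suprathreshold_count(self) -> int:
        return int(np.count_nonzero(self.zvalues > self.threshold))


@dataclass
class ComponentLabel:
    component_id: int
    artifact_flag: bool = False
    artifact_reasons: list[str] = field(default_factory=list)
    selected: bool = False
    name: str = ""


def zscale(
    source_row: np.ndarray,
    threshold: float = 2.5,
    component_id: int = 0,
    two_sided: bool = False,
) -> ZMap:
    """Scale a source row to zero mean, unit SD.

    ``two_sided=True`` thresholds on ``|Z|`` instead of ``Z`` (the default
    follows the one-sided ``Z > 2.5`` display convention).
    """
    v = np.asarray(source_row, dtype=float).ravel()
    sd = v.std()
    if sd == 0:
        raise DegenerateSourceError(
            f"component {component_id} has zero variance; cannot Z-scale"
        )
    z = (v - v.mean()) / sd
    if two_sided:
        z = np.abs(z)
    return ZMap(component_id=component_id, zvalues=z, threshold=threshold)


def mask_rim(mask: np.ndarray, edge_depth: int = 2) -> np.ndarray:
    """Boundary shell of the mask: voxels within ``edge_depth`` of its edge."""
    mask = np.asarray(mask, dtype=bool)
    eroded = binary_erosion(mask, iterations=edge_depth) if edge_depth > 0 else mask
    return mask & ~eroded


def flag_artifacts(
    zmap: ZMap,
    mask: np.ndarray,
    gm_reference: np.ndarray | None = None,
    edge_depth: int = 2,
    frac_limits: dict[str, float] | None = None,
) -> ComponentLabel:
    """Label a component as artifactual when its suprathreshold support is
    edge-dominated or lies outside the GM reference.

    ``frac_limits`` carries the two decision fractions
    (``{"edge": 0.5, "gm": 0.5}`` by default).
    """
    limits = {"edge": 0.5, "gm": 0.5}
    if frac_limits:
        limits.update(frac_limits)
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if zmap.zvalues.size != n_mask:
        raise DimensionMismatchError("Z map length does not match the mask")

    supra = zmap.zvalues > zmap.threshold
    label = ComponentLabel(component_id=zmap.component_id)
    if not supra.any():
        warnings.warn(
            f"component {zmap.component_id} has no suprathreshold voxels; "
            "labeling as artifact (vacuous support)"
        )
        label.artifact_flag = True
        label.artifact_reasons.append("outside_gm")
        return label

    rim_flat = mask_rim(mask, edge_depth)[mask]
    edge_frac = float(np.mean(rim_flat[supra]))
    if edge_frac > limits["edge"]:
        label.artifact_reasons.append("edge_dominated")

    if gm_reference is not None:
        gm_flat = np.asarray(gm_reference, dtype=bool)[mask]
        outside_frac = float(np.mean(~gm_flat[supra]))
        if outside_frac > limits["gm"]:
            label.artifact_reasons.append("outside_gm")

    label.artifact_flag = bool(label.artifact_reasons)
    return label


def select_components(
    labels: list[ComponentLabel],
    selection_config: dict | None = None,
    zmaps: list[ZMap] | None = None,
    roi_mask_flat: np.ndarray | None = None,
) -> list[int]:
    """Ordered ids of the components that enter the statistics.

    ``selection_config`` may contain ``components`` (explicit id list,
    order preserved) and/or ``min_overlap`` (minimum fraction of
    suprathreshold voxels inside ``roi_mask_flat``).  An empty config
    selects every non-artifact component.  Artifact components are never
    selected.
    """
    config = selection_config or {}
    unknown = set(config) - {"components", "min_overlap", "roi_mask"}
    if unknown:
        raise ConfigError(f"unknown selection keys: {sorted(unknown)}")
    by_id = {lab.component_id: lab for lab in labels}

    if "components" in config and config["components"]:
        wanted = list(config["components"])
        missing = [c for c in wanted if c not in by_id]
        if missing:
            raise ConfigError(f"selection references unknown component ids: {missing}")
        candidates = wanted
    else:
        candidates = [lab.component_id for lab in labels]

    min_overlap = config.get("min_overlap")
    if min_overlap is not None:
        if roi_mask_flat is None or zmaps is None:
            raise ConfigError(
                "min_overlap selection requires an ROI mask and the Z maps"
            )
        roi = np.asarray(roi_mask_flat, dtype=bool)
        zmap_by_id = {z.component_id: z for z in zmaps}
        kept = []
        for cid in candidates:
            supra = zmap_by_id[cid].zvalues > zmap_by_id[cid].threshold
            if supra.any() and float(np.mean(roi[supra])) >= min_overlap:
                kept.append(cid)
        candidates = kept

    selected = [cid for cid in candidates if not by_id[cid].artifact_flag]
    for cid in selected:
        by_id[cid].selected = True
    return selected
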