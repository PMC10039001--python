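"""Reference-guided alignment of disarticulated cranial fragments (DTA).

Two fragments of one cranium, digitised in unrelated coordinate frames
and with no conjoining points, cannot be re-assembled directly. The
protocol here ranks a comparative sample of complete crania by their
morphological affinity to the fragments (symmetrisation, size-matching,
Procrustes registration, cumulative Euclidean distance) and then uses the
best-ranked specimen as a spatial template: each fragment is rigidly
registered (rotation + translation only, both fragments belong to one
individual) onto the matching sub-configuration of the scaled template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import (
    InvalidLandmarksError,
    LandmarkConfiguration,
    centroid_size,
    cumulative_euclidean_distance,
    procrustes_distance,
)
from .meshes import TriMesh
from .procrustes import SimilarityTransform, opa_align, symmetrise
from .tps import estimate_missing_landmarks

logger = logging.getLogger(__name__)

__all__ = ["rank_references", "align_fragments", "reconstruct_specimen", "Reconstruction"]

RANKING_COLUMNS = [
    "reference_id",
    "euclidean_a",
    "euclidean_b",
    "procrustes_a",
    "procrustes_b",
    "combined_score",
    "rank",
]


def _maybe_symmetrise(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Symmetrise when a usable pairing table is present, else pass through."""
    if config.missing_mask.any():
        logger.warning(
            "%s has missing landmarks; skipping symmetrisation", config.specimen_id
        )
        return config
    if config.pairing is not None and len(config.pairing.midline) >= 3:
        return symmetrise(config)
    logger.warning(
        "no usable pairing table for %s; skipping symmetrisation", config.specimen_id
    )
    return config


def _fragment_affinity(
    fragment: LandmarkConfiguration, reference: LandmarkConfiguration
) -> tuple[float, float]:
    """(cumulative Euclidean mm, Procrustes distance) of a reference's
    sub-configuration registered onto one fragment."""
    ref_sub = reference.subset(fragment.landmark_names)
    ref_sub.pairing = fragment.pairing
    frag_s = _maybe_symmetrise(fragment)
    ref_s = _maybe_symmetrise(ref_sub)
    # scale the reference sub-configuration to the fragment's size
    s = centroid_size(frag_s) / centroid_size(ref_s)
    centre = ref_s.coords.mean(axis=0)
    ref_scaled = ref_s.with_coords((ref_s.coords - centre) * s + centre)
    # rigid Procrustes registration of the scaled reference onto the fragment
    _, aligned, _ = opa_align(ref_scaled, frag_s, allow_scaling=False)
    eu = cumulative_euclidean_distance(aligned, frag_s)
    pd_ = procrustes_distance(aligned, frag_s)
    return eu, pd_


def rank_references(
    pair, references: list[LandmarkConfiguration]
) -> pd.DataFrame:
    """Rank complete reference specimens by affinity to both fragments.

    Per reference and fragment: symmetrise, scale the reference
    sub-configuration to the fragment's centroid size, register rigidly,
    and measure cumulative Euclidean and Procrustes distances. The
    combined score is the sum of the two fragments' cumulative Euclidean
    distances; ties break on the Procrustes sum, then reference id.
    References lacking required landmarks are skipped with a warning.
    """
    required = set(pair.frag_a.landmark_names) | set(pair.frag_b.landmark_names)
    rows = []
    for ref in references:
        if not required <= set(ref.landmark_names) or ref.missing_mask[
            [ref.index_of(n) for n in required]
        ].any():
            logger.warning(
                "reference %s lacks required landmarks; skipped", ref.specimen_id
            )
            continue
        eu_a, pd_a = _fragment_affinity(pair.frag_a, ref)
        eu_b, pd_b = _fragment_affinity(pair.frag_b, ref)
        rows.append(
            {
                "reference_id": ref.specimen_id,
                "euclidean_a": eu_a,
                "euclidean_b": eu_b,
                "procrustes_a": pd_a,
                "procrustes_b": pd_b,
                "combined_score": eu_a + eu_b,
            }
        )
    if not rows:
        raise InvalidLandmarksError("no usable reference specimens")
    df = pd.DataFrame(rows)
    df["_pd_sum"] = df["procrustes_a"] + df["procrustes_b"]
    df = df.sort_values(
        ["combined_score", "_pd_sum", "reference_id"], kind="mergesort"
    ).drop(columns="_pd_sum")
    df["rank"] = np.arange(1, len(df) + 1)
    return df[RANKING_COLUMNS].reset_index(drop=True)


def align_fragments(
    pair, reference: LandmarkConfiguration
) -> tuple[LandmarkConfiguration, SimilarityTransform, SimilarityTransform]:
    """Re-assemble the two fragments in the reference's frame.

    The reference is scaled once to the fragments' combined centroid size
    (computed pose-invariantly as sqrt(cs_a^2 + cs_b^2) over each
    fragment's own centroid), then each fragment is registered onto the
    corresponding reference sub-configuration by rotation and translation
    only: the fragments belong to one individual, so their mutual scale is
    preserved. Returns the merged configuration and the two rigid
    transforms (applicable to the fragments' meshes).
    """
    names_a = pair.frag_a.landmark_names
    names_b = pair.frag_b.landmark_names
    required = set(names_a) | set(names_b)
    if not required <= set(reference.landmark_names):
        missing = sorted(required - set(reference.landmark_names))
        raise InvalidLandmarksError(f"reference lacks landmarks: {missing}")

    ref_a = reference.subset(names_a)
    ref_b = reference.subset(names_b)
    cs_frag = np.hypot(centroid_size(pair.frag_a), centroid_size(pair.frag_b))
    cs_ref = np.hypot(centroid_size(ref_a), centroid_size(ref_b))
    s = cs_frag / cs_ref

    # scale the whole reference once about the centroid of the union
    union_names = list(names_a) + list(names_b)
    ref_union = reference.subset(union_names)
    centre = ref_union.coords.mean(axis=0)
    scaled_coords = (ref_union.coords - centre) * s + centre
    ref_scaled = ref_union.with_coords(scaled_coords)

    ref_a_scaled = ref_scaled.subset(names_a)
    ref_b_scaled = ref_scaled.subset(names_b)

    t_a, aligned_a, _ = opa_align(pair.frag_a, ref_a_scaled, allow_scaling=False)
    t_b, aligned_b, _ = opa_align(pair.frag_b, ref_b_scaled, allow_scaling=False)

    merged = LandmarkConfiguration(
        specimen_id=f"{pair.frag_a.specimen_id}+{pair.frag_b.specimen_id}",
        landmark_names=union_names,
        coords=np.vstack([aligned_a.coords, aligned_b.coords]),
        missing_mask=np.concatenate(
            [pair.frag_a.missing_mask, pair.frag_b.missing_mask]
        ),
        estimated_mask=np.concatenate(
            [pair.frag_a.estimated_mask, pair.frag_b.estimated_mask]
        ),
    )
    return merged, t_a, t_b


@dataclass
class Reconstruction:
    """One template-guided virtual reconstruction of a fragmented specimen."""

    template_id: str
    merged: LandmarkConfiguration
    transform_a: SimilarityTransform
    transform_b: SimilarityTransform
    mesh_a: TriMesh | None = None
    mesh_b: TriMesh | None = None


def reconstruct_specimen(
    pair, templates: list[LandmarkConfiguration]
) -> list[Reconstruction]:
    """Full reconstruction against one or more complete templates.

    For each template: estimate any missing fragment landmarks from the
    template, align the fragments, and transform the fragment meshes (when
    present) into the merged frame. Template landmarks absent from both
    fragments (e.g. bone lost along the break) are estimated in the merged
    frame and appended, flagged in ``estimated_mask``, so the merged
    configuration always carries the template's full landmark set. Each
    bundle records its template.
    """
    if not templates:
        raise InvalidLandmarksError("at least one template is required")
    out = []
    for template in templates:
        frag_a, frag_b = pair.frag_a, pair.frag_b
        if frag_a.missing_mask.any():
            frag_a = estimate_missing_landmarks(frag_a, template.subset(frag_a.landmark_names))
        if frag_b.missing_mask.any():
            frag_b = estimate_missing_landmarks(frag_b, template.subset(frag_b.landmark_names))
        completed = type(pair)(
            frag_a=frag_a,
            frag_b=frag_b,
            mesh_a=pair.mesh_a,
            mesh_b=pair.mesh_b,
            source_id=pair.source_id,
        )
        merged, t_a, t_b = align_fragments(completed, template)
        lost = [
            n for n in template.landmark_names if n not in merged.landmark_names
        ]
        if lost:
            names = merged.landmark_names + lost
            coords = np.vstack([merged.coords, np.full((len(lost), 3), np.nan)])
            partial = LandmarkConfiguration(
                specimen_id=merged.specimen_id,
                landmark_names=names,
                coords=coords,
                estimated_mask=np.concatenate(
                    [merged.estimated_mask, np.zeros(len(lost), dtype=bool)]
                ),
            )
            merged = estimate_missing_landmarks(partial, template.subset(names))
        out.append(
            Reconstruction(
                template_id=template.specimen_id,
                merged=merged,
                transform_a=t_a,
                transform_b=t_b,
                mesh_a=pair.mesh_a.transformed(t_a) if pair.mesh_a is not None else None,
                mesh_b=pair.mesh_b.transformed(t_b) if pair.mesh_b is not None else None,
            )
        )
    return out
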