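"""Registration quality metrics: inverse consistency (VME, IME) and Dice of
composed deformations, plus a cohort evaluation harness.

Inverse consistency composes two independently estimated transforms, one per
registration direction; the closer the composition is to identity, the
better.  VME measures the composed displacement in mm, IME the induced fat
content change in percentage points, and the composed Dice the overlap of
50%-thresholded fat/water masks before and after the composed deformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imagecore import BinaryMask, ScalarVolume, dice, interpolate, resample, threshold_mask
from .registration import RegistrationConfig, register_whole_body
from .subject import BODYPART_NAMES, SubjectRecord
from .transforms import CompositeTransform, SpatialTransform


def _composed_points(t_ab: SpatialTransform, t_ba: SpatialTransform, pts: np.ndarray):
    mid = pts if t_ab is None else t_ab(pts)
    return mid if t_ba is None else t_ba(mid)


def vme(
    t_ab: SpatialTransform | None,
    t_ba: SpatialTransform | None,
    domain: BinaryMask,
) -> float:
    """Vector magnitude error: mean |x − T_ba(T_ab(x))| (mm) over the domain.

    The transforms must be oriented so their composition maps domain points
    back into the domain's space.
    """
    idx = np.argwhere(domain.as_bool())
    if idx.size == 0:
        raise ValueError("empty evaluation domain")
    pts = domain.grid.index_to_physical(idx)
    out = _composed_points(t_ab, t_ba, pts)
    return float(np.mean(np.linalg.norm(out - pts, axis=1)))


def ime(
    t_ab: SpatialTransform | None,
    t_ba: SpatialTransform | None,
    intensity: ScalarVolume,
    domain: BinaryMask,
) -> float:
    """Intensity magnitude error: mean |I(x) − I(T_ba(T_ab(x)))| over the
    domain; computed on fat content (%).  Composed points that land outside
    the volume use the fill-value contract (0, air)."""
    idx = np.argwhere(domain.as_bool())
    if idx.size == 0:
        raise ValueError("empty evaluation domain")
    pts = domain.grid.index_to_physical(idx)
    out = _composed_points(t_ab, t_ba, pts)
    vals0 = intensity.values[domain.as_bool()]
    vals1 = interpolate(intensity, out)
    return float(np.mean(np.abs(vals0 - vals1)))


def composed_dice(
    t_ab: SpatialTransform | None,
    t_ba: SpatialTransform | None,
    content: ScalarVolume,
    cutoff: float = 50.0,
) -> float:
    """Dice of the content mask before vs after the composed deformation."""
    before = threshold_mask(content, cutoff)
    members = [t for t in (t_ba, t_ab) if t is not None]
    if members:
        warped = resample(content, CompositeTransform(members), content.grid)
    else:
        warped = content
    after = threshold_mask(ScalarVolume.like(content, warped.values), cutoff)
    return dice(before, after)


@dataclass
class EvaluationReport:
    """Per-subject rows and cohort summary of the inverse-consistency metrics."""

    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return (
            self.rows.groupby(["bodypart", "metric"])["value"]
            .agg(["mean", "std", "count"])
            .rename(columns={"std": "sd", "count": "n"})
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def whole_body(self, metric: str) -> float:
        sel = self.rows[(self.rows.bodypart == "whole_body") & (self.rows.metric == metric)]
        return float(sel.value.mean())


def _metrics_for_domain(t1, t2, subject: SubjectRecord) -> list:
    """VME/IME/Dice per bodypart + voxel-weighted whole body, with the domain
    (and bodypart labels) taken from ``subject`` — the space the composition
    maps back into."""
    out = []
    domains = {"whole_body": subject.body}
    for part, name in BODYPART_NAMES.items():
        region = subject.bodyparts.region(part)
        if region.n_voxels:
            domains[name] = region
    for name, dom in domains.items():
        out.append((name, "vme_mm", vme(t1, t2, dom)))
        out.append((name, "ime_pct", ime(t1, t2, subject.fat, dom)))
    composed = CompositeTransform([t2, t1])
    for content, metric in ((subject.fat, "dice_fat"), (subject.water, "dice_wat")):
        before = threshold_mask(content, 50.0)
        warped = resample(content, composed, content.grid)
        after = threshold_mask(ScalarVolume.like(content, warped.values), 50.0)
        out.append(("whole_body", metric, dice(before, after)))
        for part, pname in BODYPART_NAMES.items():
            region = subject.bodyparts.region(part).as_bool()
            if not region.any():
                continue
            b = BinaryMask(
                (before.as_bool() & region).astype(np.uint8), content.spacing, content.origin
            )
            a = BinaryMask(
                (after.as_bool() & region).astype(np.uint8), content.spacing, content.origin
            )
            out.append((pname, metric, dice(b, a)))
    return out


def evaluate_cohort(
    subjects: list,
    reference: SubjectRecord,
    config: RegistrationConfig | None = None,
) -> EvaluationReport:
    """Register every subject to the reference in both directions and report
    inverse consistency for both composition orders.

    Each subject A yields transforms T(ref→A) (fixed = reference) and
    T(A→ref) (fixed = A); the order T(A→ref)∘T(ref→A) is evaluated on the
    reference's bodyparts, the reverse order on the subject's.  Failed
    subjects are recorded and skipped, not fatal.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject besides the reference")
    if config is None:
        config = RegistrationConfig()
    rows = []
    failures = []
    for subj in subjects:
        try:
            fwd = register_whole_body(reference, subj, config).transform  # ref -> subj
            rev = register_whole_body(subj, reference, config).transform  # subj -> ref
            for part, metric, value in _metrics_for_domain(fwd, rev, reference):
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "order": "ref_first",
                        "bodypart": part,
                        "metric": metric,
                        "value": value,
                    }
                )
            for part, metric, value in _metrics_for_domain(rev, fwd, subj):
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "order": "subject_first",
                        "bodypart": part,
                        "metric": metric,
                        "value": value,
                    }
                )
        except Exception as exc:  # noqa: BLE001 - failed subjects are reported
            failures.append((subj.subject_id, repr(exc)))
    report = EvaluationReport(pd.DataFrame(rows))
    report.failures = failures
    return report
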