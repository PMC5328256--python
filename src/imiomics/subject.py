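"""Per-subject data model: the volume set, landmarks and covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

from .imagecore import BinaryMask, LabelVolume, ScalarVolume
from .transforms import LandmarkSet

#: Bodypart label dictionary (0 = background).  The torso part contains the
#: spine and is the one allowed a slightly elastic deformation in step 1;
#: lower arms are not modelled.
BODYPART_NAMES = {
    1: "lower_leg_left",
    2: "lower_leg_right",
    3: "upper_leg_left",
    4: "upper_leg_right",
    5: "pelvis",
    6: "torso",
    7: "head",
    8: "upper_arm_left",
    9: "upper_arm_right",
}

#: The torso/spine bodypart registered with an elastic (B-spline) transform.
SPINE_PART = 6

#: Landmarks guiding each bodypart's bone registration (1, 2 or 4 closest).
PART_LANDMARKS = {
    1: ("ankle_left", "knee_left"),
    2: ("ankle_right", "knee_right"),
    3: ("knee_left", "femoral_head_left"),
    4: ("knee_right", "femoral_head_right"),
    5: ("femoral_head_left", "femoral_head_right"),
    6: ("femoral_head_left", "femoral_head_right", "humeral_head_left", "humeral_head_right"),
    7: ("humeral_head_left", "humeral_head_right"),
    8: ("humeral_head_left",),
    9: ("humeral_head_right",),
}


@dataclass
class SubjectRecord:
    """One subject: fat/water content (%), masks, bodyparts, 8 landmarks.

    All volumes must share one grid; landmarks are physical mm.
    """

    subject_id: str
    fat: ScalarVolume
    water: ScalarVolume
    body: BinaryMask
    bone: BinaryMask
    bodyparts: LabelVolume
    landmarks: LandmarkSet
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        ref = self.fat
        for name in ("water", "body", "bone", "bodyparts"):
            vol = getattr(self, name)
            if not ref.same_geometry(vol):
                raise ValueError(
                    f"subject {self.subject_id!r}: geometry of {name} does not match fat "
                    f"(shape {vol.shape} vs {ref.shape}, spacing {vol.spacing} vs {ref.spacing})"
                )

    @property
    def grid(self):
        return self.fat.grid
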