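"""Linear gradient-elution programs and their descriptor sets.

A gradient run is a single-segment linear ramp of the organic-modifier
volume fraction phi and/or the eluent pH, from initial to final value over
the gradient time ``t_g`` (minutes), after which the instrument holds the
final composition.  Three families of runs are bundled with the package:

* dataset A  -- 19 phi gradients at constant pH (phi 0.20 -> 0.50),
* dataset B  -- 22 pH gradients at constant phi (pH up-ramps),
* dataset C  -- 27 double pH/phi gradients on a three-level full factorial
  in (pH_f, phi_f, t_g) with fixed phi_i = 0.25 and pH_i = 3.21.

Datasets A and B are stored slope-first: the printed descriptors
(pH_i, dpH/dt, phi_i, dphi/dt) are authoritative, and the ramp endpoints /
gradient time are reconstructed only when an elution simulation needs them
(dataset A ends at phi_f = 0.5; dataset B runs ramp to pH 10.7 for runs
1B-10B and to pH 9.0 for 11B-22B).

The descriptors a retention model actually uses depend on the modeling
context: constant columns carry no information and are excluded, so dataset
A is described by (pH_i, dphi/dt), B by (pH_i, dpH/dt, phi_i), the fused
A+B set by all four, and the factorial dataset C by the raw design factors
(pH_f, phi_f, t_g).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVE_DESCRIPTORS",
    "DesignTable",
    "GradientDescriptors",
    "GradientProfile",
    "InvalidProfileError",
    "composition_at",
    "compute_descriptors",
    "factorial_design_C",
    "load_design_fixture",
]

#: Descriptor names (in fixed order) that act as model inputs per modeling
#: context.  The order here defines the column order of feature matrices.
ACTIVE_DESCRIPTORS: dict[str, tuple[str, ...]] = {
    "A": ("pH_i", "dphi_dt"),
    "B": ("pH_i", "dpH_dt", "phi_i"),
    "A+B": ("pH_i", "dpH_dt", "phi_i", "dphi_dt"),
    "C": ("pH_f", "phi_f", "t_g"),
}

_SPLITS = ("train", "val", "test", "unassigned")

#: Factor levels of the dataset C three-level full factorial.
C_LEVELS: dict[str, tuple[float, ...]] = {
    "pH_f": (4.68, 5.86, 7.86),
    "phi_f": (0.35, 0.40, 0.50),
    "t_g": (10.0, 20.0, 30.0),
}
C_FIXED: dict[str, float] = {"phi_i": 0.25, "pH_i": 3.21}

# Split assignment for the factorial runs (run ids are lexicographic in
# (pH_f, phi_f, t_g)).  The 6 test and 4 validation runs are spread over the
# factor cube: test takes four opposing corners plus the two t_g extremes of
# the cube centre; validation takes four face centres.  Users may override
# via the split column of a design CSV.
C_SPLIT: dict[str, str] = {
    "C03": "test",   # (4.68, 0.35, 30)
    "C07": "test",   # (4.68, 0.50, 10)
    "C19": "test",   # (7.86, 0.35, 10)
    "C27": "test",   # (7.86, 0.50, 30)
    "C13": "test",   # (5.86, 0.40, 10)
    "C15": "test",   # (5.86, 0.40, 30)
    "C05": "val",    # (4.68, 0.40, 20)
    "C11": "val",    # (5.86, 0.35, 20)
    "C17": "val",    # (5.86, 0.50, 20)
    "C23": "val",    # (7.86, 0.40, 20)
}


class InvalidProfileError(ValueError):
    """Raised when a gradient program violates its physical constraints."""


@dataclass(frozen=True)
class GradientProfile:
    """One run's eluent program: linear ramp then hold.

    ``dphi_dt`` / ``dpH_dt`` optionally carry the printed slope of the
    source design table; when present they are authoritative for descriptor
    computation (endpoints are then derived quantities).
    """

    run_id: str
    dataset_tag: str
    phi_i: float
    phi_f: float
    pH_i: float
    pH_f: float
    t_g: float
    split: str = "unassigned"
    dphi_dt: float | None = None
    dpH_dt: float | None = None

    def __post_init__(self) -> None:
        if self.dataset_tag not in ("A", "B", "C"):
            raise InvalidProfileError(
                f"{self.run_id}: unknown dataset_tag {self.dataset_tag!r}"
            )
        if self.split not in _SPLITS:
            raise InvalidProfileError(f"{self.run_id}: unknown split {self.split!r}")
        if not self.t_g > 0:
            raise InvalidProfileError(f"{self.run_id}: t_g must be > 0, got {self.t_g}")
        if not (0 < self.phi_i <= self.phi_f < 1):
            raise InvalidProfileError(
                f"{self.run_id}: need 0 < phi_i <= phi_f < 1, "
                f"got phi_i={self.phi_i}, phi_f={self.phi_f}"
            )
        for name in ("pH_i", "pH_f"):
            v = getattr(self, name)
            if not (1 < v <= 12):
                raise InvalidProfileError(f"{self.run_id}: {name}={v} outside (1, 12]")
        if self.dataset_tag == "A" and self.pH_f != self.pH_i:
            raise InvalidProfileError(f"{self.run_id}: dataset A runs hold pH constant")
        if self.dataset_tag == "B" and self.phi_f != self.phi_i:
            raise InvalidProfileError(f"{self.run_id}: dataset B runs hold phi constant")
        for slope, lo, hi in (
            (self.dphi_dt, self.phi_i, self.phi_f),
            (self.dpH_dt, self.pH_i, self.pH_f),
        ):
            if slope is not None and abs(lo + slope * self.t_g - hi) > 1e-9:
                raise InvalidProfileError(
                    f"{self.run_id}: stored slope inconsistent with endpoints"
                )

    @classmethod
    def from_slopes(
        cls,
        run_id: str,
        dataset_tag: str,
        pH_i: float,
        dpH_dt: float,
        phi_i: float,
        dphi_dt: float,
        split: str = "unassigned",
        *,
        phi_f: float | None = None,
        pH_f: float | None = None,
        t_g: float | None = None,
    ) -> "GradientProfile":
        """Build a profile from printed descriptors plus one ramp endpoint.

        ``t_g`` is reconstructed from whichever slope is non-zero and its
        endpoint; for a fully isocratic program ``t_g`` must be given.
        """
        if t_g is None:
            if dphi_dt != 0:
                if phi_f is None:
                    raise InvalidProfileError(f"{run_id}: phi_f needed to derive t_g")
                t_g = (phi_f - phi_i) / dphi_dt
            elif dpH_dt != 0:
                if pH_f is None:
                    raise InvalidProfileError(f"{run_id}: pH_f needed to derive t_g")
                t_g = (pH_f - pH_i) / dpH_dt
            else:
                raise InvalidProfileError(
                    f"{run_id}: isocratic program needs an explicit t_g"
                )
        if phi_f is None:
            phi_f = phi_i + dphi_dt * t_g
        if pH_f is None:
            pH_f = pH_i + dpH_dt * t_g
        return cls(
            run_id=run_id,
            dataset_tag=dataset_tag,
            phi_i=phi_i,
            phi_f=phi_f,
            pH_i=pH_i,
            pH_f=pH_f,
            t_g=t_g,
            split=split,
            dphi_dt=dphi_dt,
            dpH_dt=dpH_dt,
        )

    def with_split(self, split: str) -> "GradientProfile":
        return replace(self, split=split)


@dataclass(frozen=True)
class GradientDescriptors:
    """Descriptor set of one gradient run plus the active-input selection."""

    pH_i: float
    dpH_dt: float
    phi_i: float
    dphi_dt: float
    pH_f: float
    phi_f: float
    t_g: float
    active: tuple[str, ...]

    def active_values(self) -> np.ndarray:
        """Active descriptors as a vector, in the documented fixed order."""
        return np.array([getattr(self, name) for name in self.active], dtype=float)


def compute_descriptors(
    profile: GradientProfile, context_tag: str | None = None
) -> GradientDescriptors:
    """Descriptors of a run; which are model inputs depends on the context.

    ``context_tag`` defaults to the profile's own dataset tag; pass ``"A+B"``
    when the run belongs to the fused phi + pH gradient collection.
    """
    tag = profile.dataset_tag if context_tag is None else context_tag
    if tag not in ACTIVE_DESCRIPTORS:
        raise InvalidProfileError(f"unknown modeling context {tag!r}")
    if not profile.t_g > 0:  # defensive; profiles validate on construction
        raise InvalidProfileError(f"{profile.run_id}: t_g must be > 0")
    dphi = (
        profile.dphi_dt
        if profile.dphi_dt is not None
        else (profile.phi_f - profile.phi_i) / profile.t_g
    )
    dpH = (
        profile.dpH_dt
        if profile.dpH_dt is not None
        else (profile.pH_f - profile.pH_i) / profile.t_g
    )
    return GradientDescriptors(
        pH_i=profile.pH_i,
        dpH_dt=dpH,
        phi_i=profile.phi_i,
        dphi_dt=dphi,
        pH_f=profile.pH_f,
        phi_f=profile.phi_f,
        t_g=profile.t_g,
        active=ACTIVE_DESCRIPTORS[tag],
    )


def composition_at(profile: GradientProfile, t: float) -> tuple[float, float]:
    """Eluent composition ``(phi, pH)`` delivered at time ``t`` minutes.

    Linear interpolation over ``[0, t_g]``; the final composition is held
    for ``t > t_g``.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    frac = min(t, profile.t_g) / profile.t_g
    phi = profile.phi_i + (profile.phi_f - profile.phi_i) * frac
    pH = profile.pH_i + (profile.pH_f - profile.pH_i) * frac
    return phi, pH


@dataclass
class DesignTable:
    """Ordered collection of gradient runs forming one experimental design."""

    profiles: list[GradientProfile]
    tag: str
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.run_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate run_ids in design: {dupes}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, run_id: str) -> GradientProfile:
        for p in self.profiles:
            if p.run_id == run_id:
                return p
        raise KeyError(run_id)

    def subset(self, split: str) -> list[GradientProfile]:
        return [p for p in self.profiles if p.split == split]

    def split_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.profiles:
            out[p.split] = out.get(p.split, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            rows.append(
                {
                    "run_id": p.run_id,
                    "dataset_tag": p.dataset_tag,
                    "phi_i": p.phi_i,
                    "phi_f": p.phi_f,
                    "pH_i": p.pH_i,
                    "pH_f": p.pH_f,
                    "t_g": p.t_g,
                    "split": p.split,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tag: str | None = None,
                   provenance: str = "") -> "DesignTable":
        """Parse a design table in endpoint form or slope form.

        Endpoint form carries ``phi_f,pH_f,t_g``; slope form carries
        ``dphi_dt,dpH_dt`` (and whichever endpoints are needed to pin down
        ``t_g``).  Missing split labels default to ``unassigned``.
        """
        profiles = []
        slope_form = "dphi_dt" in frame.columns or "dpH_dt" in frame.columns
        for _, row in frame.iterrows():
            split = row.get("split", "unassigned")
            if pd.isna(split) or split == "":
                split = "unassigned"
            common = dict(
                run_id=str(row["run_id"]),
                dataset_tag=str(row["dataset_tag"]),
                split=str(split),
            )
            def _opt(name):
                v = row.get(name)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
            if slope_form:
                profiles.append(
                    GradientProfile.from_slopes(
                        pH_i=float(row["pH_i"]),
                        dpH_dt=float(row.get("dpH_dt", 0.0) or 0.0),
                        phi_i=float(row["phi_i"]),
                        dphi_dt=float(row.get("dphi_dt", 0.0) or 0.0),
                        phi_f=_opt("phi_f"),
                        pH_f=_opt("pH_f"),
                        t_g=_opt("t_g"),
                        **common,
                    )
                )
            else:
                profiles.append(
                    GradientProfile(
                        phi_i=float(row["phi_i"]),
                        phi_f=float(row["phi_f"]),
                        pH_i=float(row["pH_i"]),
                        pH_f=float(row["pH_f"]),
                        t_g=float(row["t_g"]),
                        **common,
                    )
                )
        if tag is None:
            tags = {p.dataset_tag for p in profiles}
            tag = tags.pop() if len(tags) == 1 else "A+B"
        return cls(profiles=profiles, tag=tag, provenance=provenance)

    @classmethod
    def from_csv(cls, path, tag: str | None = None) -> "DesignTable":
        return cls.from_frame(pd.read_csv(path), tag=tag, provenance=str(path))


def factorial_design_C(assign_splits: bool = False) -> DesignTable:
    """The 27-run three-level full factorial of double pH/phi gradients.

    Runs are ordered lexicographically in (pH_f, phi_f, t_g) and labelled
    ``C01`` ... ``C27``.  With ``assign_splits`` the packaged 17/4/6
    train/val/test assignment is applied, otherwise all runs are
    ``unassigned``.
    """
    profiles = []
    for i, (pH_f, phi_f, t_g) in enumerate(
        itertools.product(C_LEVELS["pH_f"], C_LEVELS["phi_f"], C_LEVELS["t_g"]), 1
    ):
        run_id = f"C{i:02d}"
        split = C_SPLIT.get(run_id, "train") if assign_splits else "unassigned"
        profiles.append(
            GradientProfile(
                run_id=run_id,
                dataset_tag="C",
                phi_i=C_FIXED["phi_i"],
                phi_f=phi_f,
                pH_i=C_FIXED["pH_i"],
                pH_f=pH_f,
                t_g=t_g,
                split=split,
            )
        )
    return DesignTable(
        profiles=profiles,
        tag="C",
        provenance="three-level factorial in (pH_f, phi_f, t_g)",
    )


def load_design_fixture(tag: str) -> DesignTable:
    """Packaged gradient designs with their train/val/test split labels.

    ``A`` -> 19 phi gradients (10/3/6), ``B`` -> 22 pH gradients (12/4/6),
    ``C`` -> 27 double gradients (17/4/6), ``A+B`` -> concatenation of A and
    B with labels preserved.
    """
    if tag == "C":
        return factorial_design_C(assign_splits=True)
    if tag == "A+B":
        a, b = load_design_fixture("A"), load_design_fixture("B")
        return DesignTable(
            profiles=a.profiles + b.profiles,
            tag="A+B",
            provenance="fusion of packaged designs A and B",
        )
    if tag not in ("A", "B"):
        raise ValueError(f"unknown design tag {tag!r}")
    with resources.files("gradret.data").joinpath("design_AB.csv").open() as fh:
        frame = pd.read_csv(fh)
    frame = frame[frame["dataset_tag"] == tag]
    return DesignTable.from_frame(frame, tag=tag, provenance="packaged design table")
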