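"""2D physiological state space: descriptor geometry and position scores.

A transcriptome is projected onto two axes — diurnal (light vs dark)
and growth phase (early vs late) — through a set of *state descriptor*
transcripts.  For each descriptor the reference samples define two
expression distributions, phi_alpha and phi_beta (log10 FPKM), with
medians Q2(phi_alpha) and Q2(phi_beta).  An observed log10 expression
value kappa is converted to a per-descriptor position score lambda in
[-2, 2] by a piecewise map:

* kappa inside the gap between the two distributions:
  lambda = 2 * epsilon * (theta_c - kappa) / theta,
  where theta is the gap width and theta_c its center;
* otherwise, with delta = +/-1 selecting the state whose median is
  closer and phi that state's distribution:
  lambda = 1.5*delta + epsilon*|kappa - Q2(phi)| / (2*|phi_min - Q2(phi)|)
  for kappa below the median, the analogous expression with phi_max and
  a minus sign above the median, and 1.5*delta at the median exactly.

epsilon = +1 when Q2(phi_alpha) < Q2(phi_beta) (and -1 otherwise)
orients the score so that positive lambda always means "alpha-like".
The axis coordinate is the weighted average of the per-descriptor
scores (weights convex), so |s_x|, |s_y| <= 2.

Conventions adopted here (the source equations leave them open):
values of kappa outside every observed range clamp lambda to +/-2;
an exact tie in delta with no gap yields lambda = 0 (the value the gap
interpolation takes at theta_c); alpha = light on the diurnal axis and
alpha = early on the growth axis, so positive s_x is light-like and
positive s_y is early-like.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: alpha/beta labels per axis; positive scores point at the alpha state.
AXIS_STATES = {
    "diurnal": ("light", "dark"),
    "growth_phase": ("early", "late"),
}

NON_DISTINCTIVE = "non-distinctive"


class DegenerateProfileError(ValueError):
    """The two state medians coincide; no direction can be defined."""


@dataclass(frozen=True)
class DescriptorProfile:
    """Reference geometry of one state descriptor (all in log10 FPKM)."""

    gene_id: str
    axis: str
    q2_alpha: float
    q2_beta: float
    min_alpha: float
    max_alpha: float
    min_beta: float
    max_beta: float

    def __post_init__(self) -> None:
        if self.axis not in AXIS_STATES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.q2_alpha == self.q2_beta:
            raise DegenerateProfileError(
                f"gene {self.gene_id!r}: state medians coincide "
                f"({self.q2_alpha}); not a valid descriptor"
            )
        for lo, q2, hi, name in (
            (self.min_alpha, self.q2_alpha, self.max_alpha, "alpha"),
            (self.min_beta, self.q2_beta, self.max_beta, "beta"),
        ):
            if not lo <= q2 <= hi:
                raise ValueError(
                    f"gene {self.gene_id!r}: {name} extremes do not bracket "
                    f"the median ({lo}, {q2}, {hi})"
                )

    @property
    def epsilon(self) -> int:
        """Orientation: +1 iff the alpha median lies below the beta median."""
        return 1 if self.q2_alpha < self.q2_beta else -1

    @property
    def _lower_max(self) -> float:
        """Max of the distribution with the lower median."""
        return self.max_alpha if self.epsilon == 1 else self.max_beta

    @property
    def _upper_min(self) -> float:
        """Min of the distribution with the upper median."""
        return self.min_beta if self.epsilon == 1 else self.min_alpha

    @property
    def theta(self) -> float:
        """Width of the empty interval between the two distributions (>= 0)."""
        return max(0.0, self._upper_min - self._lower_max)

    @property
    def theta_c(self) -> float | None:
        """Center of the gap; defined only when theta > 0."""
        if self.theta <= 0:
            return None
        return 0.5 * (self._lower_max + self._upper_min)

    @classmethod
    def from_samples(
        cls,
        gene_id: str,
        axis: str,
        alpha_values: Sequence[float],
        beta_values: Sequence[float],
    ) -> "DescriptorProfile":
        """Build the profile from the two per-state log10 samples."""
        a = np.asarray(alpha_values, float)
        b = np.asarray(beta_values, float)
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"gene {gene_id!r}: need >= 2 samples per state to build "
                "a profile"
            )
        return cls(
            gene_id=gene_id,
            axis=axis,
            q2_alpha=float(np.median(a)),
            q2_beta=float(np.median(b)),
            min_alpha=float(a.min()),
            max_alpha=float(a.max()),
            min_beta=float(b.min()),
            max_beta=float(b.max()),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epsilon"] = self.epsilon
        d["theta"] = self.theta
        d["theta_c"] = self.theta_c
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DescriptorProfile":
        fields = {f.name: d[f.name] for f in dataclasses.fields(cls)}
        return cls(**fields)


@dataclass
class DescriptorSet:
    """Descriptors of one axis with convex weights summing to one."""

    axis: str
    entries: list[DescriptorProfile]
    weights: np.ndarray | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.weights is None:
            n = len(self.entries)
            self.weights = np.full(n, 1.0 / n) if n else np.empty(0)
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.entries):
            raise ValueError("one weight per descriptor required")
        if self.entries:
            if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
                raise ValueError("weights must sum to 1")
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids within a descriptor set")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "pseudocount": self.pseudocount,
            "weights": [float(w) for w in self.weights],
            "entries": [e.to_dict() for e in self.entries],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DescriptorSet":
        return cls(
            axis=d["axis"],
            entries=[DescriptorProfile.from_dict(e) for e in d["entries"]],
            weights=np.asarray(d["weights"], float),
            pseudocount=float(d.get("pseudocount", 1.0)),
        )


@dataclass(frozen=True)
class PositionScoreBreakdown:
    """One descriptor's contribution to a sample's coordinate."""

    gene_id: str
    kappa: float
    delta: int
    branch: str
    lam: float


@dataclass
class StatePosition:
    """A sample's 2D coordinate with per-descriptor score breakdowns."""

    sample_id: str
    s_x: float
    s_y: float
    x_breakdown: list[PositionScoreBreakdown]
    y_breakdown: list[PositionScoreBreakdown]


def closer_state(kappa: float, profile: DescriptorProfile) -> int:
    """+1 if kappa is closer to the alpha median, -1 if to beta, 0 on a tie."""
    da = abs(kappa - profile.q2_alpha)
    db = abs(kappa - profile.q2_beta)
    if da < db:
        return 1
    if da > db:
        return -1
    return 0


def transcript_position_score(
    kappa: float, profile: DescriptorProfile
) -> PositionScoreBreakdown:
    """Per-descriptor position score lambda for an observed log10 value."""
    eps = profile.epsilon
    theta = profile.theta
    # Gap interpolation applies only strictly inside the gap; at the gap
    # edges the range interpolation takes over (the two branches agree
    # there, so the map stays continuous).
    if theta > 0 and profile._lower_max < kappa < profile._upper_min:
        lam = 2.0 * eps * (profile.theta_c - kappa) / theta
        return PositionScoreBreakdown(
            profile.gene_id, kappa, closer_state(kappa, profile), "in_gap", lam
        )
    delta = closer_state(kappa, profile)
    if delta == 0:
        # equidistant with no gap: take the value the gap interpolation
        # would assign at its center
        return PositionScoreBreakdown(profile.gene_id, kappa, 0, "at_median", 0.0)
    if delta == 1:
        q2, lo, hi = profile.q2_alpha, profile.min_alpha, profile.max_alpha
    else:
        q2, lo, hi = profile.q2_beta, profile.min_beta, profile.max_beta
    if kappa == q2:
        return PositionScoreBreakdown(
            profile.gene_id, kappa, delta, "at_median", 1.5 * delta
        )
    if kappa < q2:
        denom = 2.0 * abs(lo - q2)
        term = eps * abs(kappa - q2) / denom if denom > 0 else eps * math.inf
        lam = 1.5 * delta + term
        branch = "below_median"
    else:
        denom = 2.0 * abs(hi - q2)
        term = eps * abs(kappa - q2) / denom if denom > 0 else eps * math.inf
        lam = 1.5 * delta - term
        branch = "above_median"
    if lam > 2.0:
        lam, branch = 2.0, "clamped_high"
    elif lam < -2.0:
        lam, branch = -2.0, "clamped_low"
    return PositionScoreBreakdown(profile.gene_id, kappa, delta, branch, lam)


def map_sample_to_state_space(
    log_values: Mapping[str, float] | pd.Series,
    x_set: DescriptorSet,
    y_set: DescriptorSet,
    sample_id: str = "",
) -> StatePosition:
    """Project one log10-transformed expression vector into the state space.

    ``log_values`` must have been transformed with the same pseudocount
    the descriptor sets were built with.
    """
    missing = [
        g
        for g in x_set.gene_ids + y_set.gene_ids
        if g not in log_values
    ]
    if missing:
        raise KeyError(
            f"sample {sample_id!r}: descriptor genes absent from "
            f"expression vector: {missing[:10]}"
        )
    coords = []
    breakdowns = []
    for dset in (x_set, y_set):
        parts = [
            transcript_position_score(float(log_values[e.gene_id]), e)
            for e in dset.entries
        ]
        coord = float(
            np.dot(dset.weights, [p.lam for p in parts])
        ) if parts else 0.0
        coords.append(coord)
        breakdowns.append(parts)
    return StatePosition(sample_id, coords[0], coords[1], *breakdowns)


def map_samples(
    expr,
    x_set: DescriptorSet,
    y_set: DescriptorSet,
) -> pd.DataFrame:
    """Map every sample of an FPKM ExpressionMatrix; returns a positions table.

    The log10(FPKM + pseudocount) transform is applied internally using
    the descriptor sets' recorded pseudocount.
    """
    if x_set.pseudocount != y_set.pseudocount:
        raise ValueError("descriptor sets were built with different pseudocounts")
    log_frame = np.log10(expr.frame + x_set.pseudocount)
    rows = []
    for sid in expr.sample_ids:
        pos = map_sample_to_state_space(log_frame[sid], x_set, y_set, sid)
        rows.append({"sample_id": sid, "s_x": pos.s_x, "s_y": pos.s_y})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class ReferenceRegion:
    """Circular reference region of one physiological state."""

    state: str
    centroid: tuple[float, float]
    radius: float

    def contains(self, s_x: float, s_y: float) -> bool:
        return math.hypot(s_x - self.centroid[0], s_y - self.centroid[1]) <= self.radius


def build_reference_regions(
    positions: pd.DataFrame,
    meta,
    reference_stage: int = 1,
    conditions: Sequence[str] | None = None,
) -> dict[str, ReferenceRegion]:
    """Reference regions from the stage-1 positions of the four states.

    centroid = mean position of that state's reference samples;
    radius = 1.96 x the standard deviation of the observed positions
    about their centroid, i.e. sqrt(var(s_x) + var(s_y)) with ddof=1
    (the RMS distance of the reference scatter, so the circle covers
    ~95% of positions under Gaussian replicate scatter).  Conditions
    are pooled by default.
    """
    by_state: dict[str, list[tuple[float, float]]] = {}
    for r in meta:
        if r.stage != reference_stage:
            continue
        if conditions is not None and r.condition not in conditions:
            continue
        if r.sample_id not in positions.index:
            continue
        row = positions.loc[r.sample_id]
        by_state.setdefault(r.state, []).append((row["s_x"], row["s_y"]))
    expected = {
        f"{d}-{g}" for d in AXIS_STATES["diurnal"] for g in AXIS_STATES["growth_phase"]
    }
    missing = sorted(expected - set(by_state))
    if missing:
        raise ValueError(f"no reference samples for states: {missing}")
    regions = {}
    for state, pts in by_state.items():
        if len(pts) < 2:
            raise ValueError(
                f"state {state!r}: need >= 2 reference samples, got {len(pts)}"
            )
        arr = np.asarray(pts)
        centroid = arr.mean(axis=0)
        total_var = arr.var(axis=0, ddof=1).sum()
        regions[state] = ReferenceRegion(
            state=state,
            centroid=(float(centroid[0]), float(centroid[1])),
            radius=float(1.96 * math.sqrt(total_var)),
        )
    return regions


def classify_position(
    position: tuple[float, float] | StatePosition,
    regions: Mapping[str, ReferenceRegion],
) -> str:
    """State label of the nearest centroid if inside its region, else
    the non-distinctive area.  Exact distance ties are non-distinctive."""
    if isinstance(position, StatePosition):
        s_x, s_y = position.s_x, position.s_y
    else:
        s_x, s_y = position
    dists = {
        state: math.hypot(s_x - reg.centroid[0], s_y - reg.centroid[1])
        for state, reg in regions.items()
    }
    best = min(dists.values())
    nearest = [state for state, d in dists.items() if d == best]
    if len(nearest) != 1:
        return NON_DISTINCTIVE
    state = nearest[0]
    return state if best <= regions[state].radius else NON_DISTINCTIVE


def regions_to_json(regions: Mapping[str, ReferenceRegion], path: str | Path) -> None:
    payload = {
        state: {"centroid": list(reg.centroid), "radius": reg.radius}
        for state, reg in regions.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def regions_from_json(path: str | Path) -> dict[str, ReferenceRegion]:
    payload = json.loads(Path(path).read_text())
    return {
        state: ReferenceRegion(state, tuple(d["centroid"]), d["radius"])
        for state, d in payload.items()
    }
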