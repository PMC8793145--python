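"""Overlap-gated inductive search over the shape generator ("shape learning
trajectory").

The loop emulates iterative synthesis tuning: perturb one generator
parameter at a time, synthesize the new ensemble, and use shape
computation to calibrate the step.  Two overlap thresholds drive the
control flow:

* ``backtrack_ovl`` — if the new ensemble's overlap with the previous
  accepted one falls below this, the jump was overlarge (the change in
  typical shape is discontinuous); the step is halved and retried,
  returning close to the previous coordinates.
* ``ovl_gate`` — an expensive biological readout is only spent when the
  candidate is sufficiently *independent* of the last ensemble that was
  assayed (overlap at or below the gate); contiguous, heavily overlapping
  distributions carry no new biological information.

The readout here is a surrogate: a configurable Gaussian-bump landscape
over a fixed reference shape space, standing in for a transcriptome- or
assay-derived response.  Direction control is a simple coordinate ascent:
keep the step direction while the readout improves, otherwise reverse,
then rotate to the next parameter.

Overlap between two specific ensembles is always computed in a pooled
PCA refit of exactly that pair (comparison-specific coordinates); the
landscape, which must be stationary across the run, lives in a reference
space fitted once at the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .overlap import overlap_coefficient
from .shape_space import (
    ShapeEnsemble,
    ShapeSpaceModel,
    ensemble_from_contours,
    fit_shape_space,
    project_ensemble,
)
from .synthetic import EnsembleParams, ShapeParams, generate_ensemble

__all__ = [
    "GaussianLandscape",
    "TrajectoryConfig",
    "StepRecord",
    "TrajectoryRecord",
    "surrogate_readout",
    "run_trajectory",
    "structure_function_table",
]

_TUNABLE = ("base_radius_nm", "spike_amplitude", "spike_sharpness")
_BOUNDS = {
    "base_radius_nm": (1e-3, np.inf),
    "spike_amplitude": (0.0, 0.9),
    "spike_sharpness": (1e-3, np.inf),
}


@dataclass(frozen=True)
class GaussianLandscape:
    """Surrogate biological response: a sum of isotropic Gaussian bumps over
    reference shape-space coordinates.  Higher = more interesting."""

    centers: np.ndarray  # (n_bumps, m)
    heights: np.ndarray  # (n_bumps,)
    widths: np.ndarray  # (n_bumps,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, float)))
        object.__setattr__(self, "heights", np.atleast_1d(np.asarray(self.heights, float)))
        object.__setattr__(self, "widths", np.atleast_1d(np.asarray(self.widths, float)))
        if np.any(self.widths <= 0):
            raise ValueError("bump widths must be > 0")

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "heights": self.heights.tolist(),
            "widths": self.widths.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianLandscape":
        return cls(np.array(d["centers"]), np.array(d["heights"]), np.array(d["widths"]))


def surrogate_readout(centroid: np.ndarray, landscape: GaussianLandscape) -> float:
    """Deterministic scalar response at a shape-space coordinate."""
    x = np.asarray(centroid, dtype=float)
    d2 = np.sum((landscape.centers - x) ** 2, axis=1)
    return float(np.sum(landscape.heights * np.exp(-d2 / (2.0 * landscape.widths**2))))


@dataclass(frozen=True)
class TrajectoryConfig:
    """Configuration of one shape-learning run.

    ``step_scales`` maps tunable mean-shape parameters (any of
    base_radius_nm, spike_amplitude, spike_sharpness) to their initial
    step sizes; the search only moves along listed parameters.
    """

    start: EnsembleParams
    step_scales: dict
    ovl_gate: float = 0.05
    backtrack_ovl: float = 0.01
    max_steps: int = 50
    seed: int = 0
    m: int = 3
    n_harmonics: int = 64
    step_floor_factor: float = 1.0 / 64.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.backtrack_ovl < self.ovl_gate < 1.0:
            raise ValueError("need 0 <= backtrack_ovl < ovl_gate < 1")
        if not self.step_scales:
            raise ValueError("step_scales must name at least one tunable parameter")
        for name in self.step_scales:
            if name not in _TUNABLE:
                raise ValueError(f"unknown tunable parameter {name!r}; allowed: {_TUNABLE}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryConfig":
        d = dict(d)
        start = d.pop("start")
        mean = ShapeParams(**start.pop("mean"))
        d["start"] = EnsembleParams(mean=mean, **start)
        return cls(**d)


@dataclass
class StepRecord:
    """One proposal: what was tried, what the overlaps said, what happened."""

    step: int
    action: str  # "advance" | "backtrack" | "query"
    param: str
    direction: int  # +1 / -1
    step_size: float
    params: dict  # mean-shape parameters of the proposal
    ovl_prev: float  # overlap with previous accepted ensemble
    ovl_last_queried: float | None  # overlap with last assayed ensemble
    centroid: np.ndarray | None  # reference-space coordinate (accepted only)
    readout: float | None  # surrogate response (queried steps only)


@dataclass
class TrajectoryRecord:
    """Complete, replayable account of one run: the config (manifest), the
    reference model, every step, and the accepted ensembles' features."""

    config: TrajectoryConfig
    reference_model: ShapeSpaceModel
    steps: list[StepRecord] = field(default_factory=list)
    accepted_features: list[np.ndarray] = field(default_factory=list)
    accepted_step_ids: list[int] = field(default_factory=list)

    @property
    def queried_steps(self) -> list[StepRecord]:
        return [s for s in self.steps if s.action == "query"]

    @property
    def final_readout(self) -> float | None:
        q = self.queried_steps
        return q[-1].readout if q else None

    @property
    def initial_readout(self) -> float | None:
        q = self.queried_steps
        return q[0].readout if q else None


def _make_ensemble(ep: EnsembleParams, label: str, k: int) -> ShapeEnsemble:
    contours = generate_ensemble(ep)
    return ensemble_from_contours(label, contours, n=1024, k=k)


def _pair_ovl(a: ShapeEnsemble, b: ShapeEnsemble, m: int) -> float:
    """Overlap of two ensembles in a pooled PCA refit of exactly this pair."""
    model = fit_shape_space([a, b])
    m_eff = min(m, model.n_components)
    pa = project_ensemble(model, a, m=m_eff)
    pb = project_ensemble(model, b, m=m_eff)
    return overlap_coefficient(pa, pb).ovl


def _clamped(params: ShapeParams, name: str, value: float) -> ShapeParams:
    lo, hi = _BOUNDS[name]
    return replace(params, **{name: float(np.clip(value, lo, hi))})


def run_trajectory(cfg: TrajectoryConfig, landscape: GaussianLandscape) -> TrajectoryRecord:
    """Run the overlap-gated coordinate-ascent search.

    Identical config + landscape reproduce the record bit-for-bit: every
    ensemble seed derives from ``cfg.seed`` and the proposal index.
    """
    param_names = list(cfg.step_scales)
    steps = {p: float(cfg.step_scales[p]) for p in param_names}
    floors = {p: steps[p] * cfg.step_floor_factor for p in param_names}
    pi = 0  # index into param_names
    sign = +1
    reversed_once = False

    def ep_at(mean: ShapeParams, idx: int) -> EnsembleParams:
        return replace(cfg.start, mean=mean, seed=int((cfg.seed * 100003 + idx) % 2**31))

    current_mean = cfg.start.mean
    current = _make_ensemble(ep_at(current_mean, 0), "step-0", cfg.n_harmonics)

    ref_model = fit_shape_space([current])
    m_ref = min(cfg.m, ref_model.n_components)

    record = TrajectoryRecord(config=cfg, reference_model=ref_model)

    def centroid_of(e: ShapeEnsemble) -> np.ndarray:
        return project_ensemble(ref_model, e, m=m_ref).centroid

    # the starting ensemble is always assayed: it anchors the ascent
    start_centroid = centroid_of(current)
    start_readout = surrogate_readout(start_centroid, landscape)
    record.steps.append(
        StepRecord(
            step=0,
            action="query",
            param=param_names[pi],
            direction=sign,
            step_size=steps[param_names[pi]],
            params=_mean_dict(current_mean),
            ovl_prev=1.0,
            ovl_last_queried=0.0,
            centroid=start_centroid,
            readout=start_readout,
        )
    )
    record.accepted_features.append(current.features)
    record.accepted_step_ids.append(0)
    last_queried = current
    last_readout = start_readout

    for step_idx in range(1, cfg.max_steps + 1):
        if all(steps[p] < floors[p] for p in param_names):
            break
        name = param_names[pi]
        proposal_mean = _clamped(current_mean, name, getattr(current_mean, name) + sign * steps[name])
        try:
            proposal = _make_ensemble(ep_at(proposal_mean, step_idx), f"step-{step_idx}", cfg.n_harmonics)
        except ValueError as err:
            raise ValueError(f"generator failed at step {step_idx} ({name} {sign:+d}): {err}") from err

        ovl_prev = _pair_ovl(current, proposal, cfg.m)
        if ovl_prev < cfg.backtrack_ovl:
            # overlarge discontinuous jump: return toward previous coordinates
            steps[name] /= 2.0
            record.steps.append(
                StepRecord(
                    step=step_idx,
                    action="backtrack",
                    param=name,
                    direction=sign,
                    step_size=steps[name],
                    params=_mean_dict(proposal_mean),
                    ovl_prev=ovl_prev,
                    ovl_last_queried=None,
                    centroid=None,
                    readout=None,
                )
            )
            continue

        # accept the move
        current_mean = proposal_mean
        current = proposal
        ovl_q = _pair_ovl(last_queried, current, cfg.m)
        centroid = centroid_of(current)

        if ovl_q <= cfg.ovl_gate:
            readout = surrogate_readout(centroid, landscape)
            record.steps.append(
                StepRecord(
                    step=step_idx,
                    action="query",
                    param=name,
                    direction=sign,
                    step_size=steps[name],
                    params=_mean_dict(current_mean),
                    ovl_prev=ovl_prev,
                    ovl_last_queried=ovl_q,
                    centroid=centroid,
                    readout=readout,
                )
            )
            if readout > last_readout:
                reversed_once = False  # keep going this way
            else:
                if reversed_once:
                    pi = (pi + 1) % len(param_names)
                    sign = +1
                    reversed_once = False
                else:
                    sign = -sign
                    reversed_once = True
            last_queried = current
            last_readout = readout
        else:
            record.steps.append(
                StepRecord(
                    step=step_idx,
                    action="advance",
                    param=name,
                    direction=sign,
                    step_size=steps[name],
                    params=_mean_dict(current_mean),
                    ovl_prev=ovl_prev,
                    ovl_last_queried=ovl_q,
                    centroid=centroid,
                    readout=None,
                )
            )
        record.accepted_features.append(current.features)
        record.accepted_step_ids.append(step_idx)

    return record


def _mean_dict(p: ShapeParams) -> dict:
    return {
        "base_radius_nm": p.base_radius_nm,
        "n_spikes": p.n_spikes,
        "spike_amplitude": p.spike_amplitude,
        "spike_sharpness": p.spike_sharpness,
        "angular_jitter": p.angular_jitter,
        "roughness": p.roughness,
    }


def structure_function_table(record: TrajectoryRecord) -> pd.DataFrame:
    """Distill the run into a structure-function table.

    Greedily selects, in trajectory order, the subsequence of assayed
    ensembles that are *pairwise* independent (every pair's pooled-refit
    overlap at or below the gate) — the investigator-controlled shape
    trajectory along which readouts are comparable, as opposed to the
    densely overlapping learning trajectory itself.
    """
    cfg = record.config
    queried = record.queried_steps
    feats = {sid: f for sid, f in zip(record.accepted_step_ids, record.accepted_features)}

    selected: list[StepRecord] = []
    selected_ens: list[ShapeEnsemble] = []
    for s in queried:
        ens = ShapeEnsemble(
            label=f"step-{s.step}",
            features=feats[s.step],
            particle_ids=[str(i) for i in range(feats[s.step].shape[0])],
        )
        if all(_pair_ovl(ens, prev, cfg.m) <= cfg.ovl_gate for prev in selected_ens):
            selected.append(s)
            selected_ens.append(ens)

    rows = []
    for s in selected:
        row = {"step": s.step, "readout": s.readout}
        row.update(s.params)
        for i, c in enumerate(s.centroid):
            row[f"pc{i + 1}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
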