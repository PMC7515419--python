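"""Seeded synthetic helix-coil benchmark generator.

Builds a ground-truth ("target") ensemble and a mismatched "prior"
ensemble of helix/coil conformations, plus two parametric chemical-shift
forward models: predictor A (used on the target ensemble; its uniform
column means become the fitting targets) and predictor B (used on the
prior ensemble; A plus conformation-dependent systematic offsets plus
extra random noise).  This stands in for pairs of force-field ensembles
scored with two independent shift predictors.

Chemical-shift model per frame j, residue r, atom a:

    cs = coil_base[a] + helix_delta[a] * f_jr + Normal(0, thermal_sd)

where f_jr is the helix fraction in the window r +/- neighbor_window
(clipped at chain ends), capturing the neighbour sensitivity of shifts.
Observables are emitted for residues 2..R-1 for CA and C; CB additionally
skips a configurable exclusion mask (glycine stand-in), so the roster is
smaller than 3R.

Randomness: all draws derive from a single integer seed via named child
streams (conformations of each ensemble, thermal noise of each ensemble,
predictor-B noise, compactness proxy), so toggling one error source never
perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .ensemble import (
    AtomKind,
    ObservableLabel,
    ObservableMatrix,
    SSMatrix,
    TargetSet,
    WeightVector,
)
from .errors import ValidationError

__all__ = [
    "GeneratorConfig",
    "BenchmarkCase",
    "helix_bump_profile",
    "generate_ss_ensemble",
    "predict_shifts_A",
    "predict_shifts_B",
    "make_target_set",
    "make_benchmark_case",
    "rg_proxy",
]

# named random streams derived from the one user seed
_STREAMS = {
    "ss_target": 0,
    "ss_prior": 1,
    "thermal_target": 2,
    "thermal_prior": 3,
    "pred_b": 4,
    "rg": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a base seed."""
    try:
        code = _STREAMS[stream]
    except KeyError:
        raise ValidationError(f"unknown random stream {stream!r}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), code]))


def helix_bump_profile(
    n_residues: int = 71,
    background: float = 0.1,
    bump: float = 0.6,
    start: int = 25,
    stop: int = 45,
) -> np.ndarray:
    """Flat background propensity with one rectangular helix bump
    (``start``..``stop`` inclusive, 1-based)."""
    if not (1 <= start <= stop <= n_residues):
        raise ValidationError("bump bounds must satisfy 1 <= start <= stop <= R")
    p = np.full(n_residues, float(background))
    p[start - 1 : stop] = float(bump)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("propensities must lie in [0, 1]")
    return p


_ATOMS = (AtomKind.CA, AtomKind.CB, AtomKind.C)


def _default_predb_systematic() -> dict:
    # helix-state offsets aligned with the helix shift signs; coil unbiased
    return {
        (AtomKind.CA, "H"): 0.4,
        (AtomKind.CA, "C"): 0.0,
        (AtomKind.CB, "H"): -0.4,
        (AtomKind.CB, "C"): 0.0,
        (AtomKind.C, "H"): 0.4,
        (AtomKind.C, "C"): 0.0,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the benchmark generator (defaults are modelling
    choices at desk scale, every one overridable)."""

    n_frames: int = 4000
    n_residues: int = 71
    propensity_target: Optional[np.ndarray] = None  # default: bump 0.6 @ 25-45
    propensity_prior: Optional[np.ndarray] = None  # default: bump 0.25 @ 25-45
    min_helix_run: int = 2
    coil_base: dict = field(
        default_factory=lambda: {AtomKind.CA: 56.0, AtomKind.CB: 30.0, AtomKind.C: 176.0}
    )
    helix_delta: dict = field(
        default_factory=lambda: {AtomKind.CA: 2.6, AtomKind.CB: -0.5, AtomKind.C: 1.8}
    )
    neighbor_window: int = 1
    thermal_sd: float = 0.3
    predB_systematic: dict = field(default_factory=_default_predb_systematic)
    predB_random_sd: float = 0.3
    target_sigmas: dict = field(
        default_factory=lambda: {AtomKind.CA: 1.06, AtomKind.CB: 1.23, AtomKind.C: 1.32}
    )
    cb_excluded: tuple = (8, 18, 31, 44, 58)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.n_residues < 3:
            raise ValidationError("n_residues must be >= 3")
        if self.min_helix_run < 1:
            raise ValidationError("min_helix_run must be >= 1")
        if self.neighbor_window < 0:
            raise ValidationError("neighbor_window must be >= 0")
        if not self.thermal_sd > 0 or not self.predB_random_sd > 0:
            raise ValidationError("noise standard deviations must be > 0")
        if self.propensity_target is None:
            self.propensity_target = helix_bump_profile(self.n_residues)
        if self.propensity_prior is None:
            self.propensity_prior = helix_bump_profile(self.n_residues, bump=0.25)
        for name in ("propensity_target", "propensity_prior"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (self.n_residues,):
                raise ValidationError(
                    f"{name} must have length n_residues={self.n_residues}"
                )
            if np.any((p < 0) | (p > 1)):
                raise ValidationError(f"{name} must lie in [0, 1]")
            setattr(self, name, p)

    # -- serialization (atom-kind keys flattened to strings) ----------------

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_residues": self.n_residues,
            "propensity_target": [float(x) for x in self.propensity_target],
            "propensity_prior": [float(x) for x in self.propensity_prior],
            "min_helix_run": self.min_helix_run,
            "coil_base": {a.value: v for a, v in self.coil_base.items()},
            "helix_delta": {a.value: v for a, v in self.helix_delta.items()},
            "neighbor_window": self.neighbor_window,
            "thermal_sd": self.thermal_sd,
            "predB_systematic": {
                f"{a.value}:{s}": v for (a, s), v in self.predB_systematic.items()
            },
            "predB_random_sd": self.predB_random_sd,
            "target_sigmas": {a.value: v for a, v in self.target_sigmas.items()},
            "cb_excluded": list(self.cb_excluded),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("coil_base", "helix_delta", "target_sigmas"):
            if key in d:
                d[key] = {AtomKind(a): float(v) for a, v in d[key].items()}
        if "predB_systematic" in d:
            out = {}
            for k, v in d["predB_systematic"].items():
                atom, state = k.split(":")
                out[(AtomKind(atom), state)] = float(v)
            d["predB_systematic"] = out
        for key in ("propensity_target", "propensity_prior"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if "cb_excluded" in d:
            d["cb_excluded"] = tuple(int(x) for x in d["cb_excluded"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown generator config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _prune_short_runs(h: np.ndarray, min_run: int) -> np.ndarray:
    """Flip helix runs shorter than min_run back to coil, per row."""
    if min_run <= 1:
        return h
    out = h.copy()
    n, r = h.shape
    padded = np.zeros((n, r + 2), dtype=np.int8)
    padded[:, 1:-1] = h
    d = np.diff(padded, axis=1)
    for i in range(n):
        starts = np.flatnonzero(d[i] == 1)
        ends = np.flatnonzero(d[i] == -1)
        for s, e in zip(starts, ends):
            if e - s < min_run:
                out[i, s:e] = 0
    return out


def generate_ss_ensemble(
    propensity: np.ndarray,
    n_frames: int,
    min_helix_run: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    stream: str = "ss_target",
) -> SSMatrix:
    """Independent helix/coil frames; each residue is H with its propensity,
    then H-runs shorter than ``min_helix_run`` are flipped to C."""
    propensity = np.asarray(propensity, dtype=float)
    if np.any((propensity < 0) | (propensity > 1)):
        raise ValidationError("propensities must lie in [0, 1]")
    if rng is None:
        if seed is None:
            raise ValidationError("provide either rng or seed")
        rng = stream_rng(seed, stream)
    h = (rng.random((n_frames, len(propensity))) < propensity).astype(np.int8)
    h = _prune_short_runs(h, min_helix_run)
    codes = np.where(h == 1, "H", "C").astype("U1")
    return SSMatrix(codes=codes, frame_ids=list(range(1, n_frames + 1)))


def _observable_roster(config: GeneratorConfig) -> list[ObservableLabel]:
    """Residue-major, atom (CA, CB, C) minor; terminals dropped for all
    atoms, CB additionally drops the exclusion mask."""
    excluded = set(config.cb_excluded)
    labels = []
    for res in range(2, config.n_residues):
        for atom in _ATOMS:
            if atom is AtomKind.CB and res in excluded:
                continue
            labels.append(
                ObservableLabel(tag=f"res{res}_{atom.value}", residue_index=res, atom_kind=atom)
            )
    return labels


def _window_helix_fraction(ss: SSMatrix, window: int) -> np.ndarray:
    """Helix fraction in the clipped window r +/- window, per frame/residue."""
    h = (ss.codes == "H").astype(float)
    n, r = h.shape
    cum = np.zeros((n, r + 1))
    np.cumsum(h, axis=1, out=cum[:, 1:])
    lo = np.clip(np.arange(r) - window, 0, None)
    hi = np.clip(np.arange(r) + window + 1, None, r)
    return (cum[:, hi] - cum[:, lo]) / (hi - lo)


def predict_shifts_A(
    ss: SSMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    stream: str = "thermal_target",
) -> ObservableMatrix:
    """Forward model A: windowed-helicity linear response plus thermal noise."""
    if rng is None:
        rng = stream_rng(config.seed, stream)
    f = _window_helix_fraction(ss, config.neighbor_window)
    labels = _observable_roster(config)
    n = ss.n_frames
    values = np.empty((n, len(labels)))
    for j, lab in enumerate(labels):
        base = config.coil_base[lab.atom_kind]
        delta = config.helix_delta[lab.atom_kind]
        values[:, j] = (
            base
            + delta * f[:, lab.residue_index - 1]
            + rng.normal(0.0, config.thermal_sd, size=n)
        )
    return ObservableMatrix(values=values, labels=labels, frame_ids=list(ss.frame_ids))


def predict_shifts_B(
    ss: SSMatrix,
    config: GeneratorConfig,
    rng_thermal: np.random.Generator | None = None,
    rng_noise: np.random.Generator | None = None,
    thermal_stream: str = "thermal_prior",
) -> ObservableMatrix:
    """Forward model B: A's value plus a conformation-state-dependent
    systematic offset plus independent random error."""
    if rng_thermal is None:
        rng_thermal = stream_rng(config.seed, thermal_stream)
    if rng_noise is None:
        rng_noise = stream_rng(config.seed, "pred_b")
    base = predict_shifts_A(ss, config, rng=rng_thermal)
    values = base.values.copy()
    for j, lab in enumerate(base.labels):
        col_state = ss.codes[:, lab.residue_index - 1]
        offs = np.where(
            col_state == "H",
            config.predB_systematic.get((lab.atom_kind, "H"), 0.0),
            config.predB_systematic.get((lab.atom_kind, "C"), 0.0),
        )
        values[:, j] = (
            values[:, j] + offs + rng_noise.normal(0.0, config.predB_random_sd, size=len(offs))
        )
    return ObservableMatrix(values=values, labels=base.labels, frame_ids=list(ss.frame_ids))


def make_target_set(target_cs_A: ObservableMatrix, config: GeneratorConfig) -> TargetSet:
    """Targets are uniform-weight column means of the target ensemble's
    predictor-A shifts; sigmas follow the atom kind."""
    values = target_cs_A.values.mean(axis=0)
    sigmas = np.array(
        [config.target_sigmas[lab.atom_kind] for lab in target_cs_A.labels]
    )
    return TargetSet(labels=list(target_cs_A.labels), values=values, sigmas=sigmas)


@dataclass
class BenchmarkCase:
    """A complete synthetic fitting problem."""

    target_cs: ObservableMatrix
    target_ss: SSMatrix
    prior_cs: ObservableMatrix
    prior_ss: SSMatrix
    targets: TargetSet
    truth: GeneratorConfig
    target_in_support: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def all_targets_in_support(self) -> bool:
        return bool(np.all(self.target_in_support))


def make_benchmark_case(config: GeneratorConfig | None = None) -> BenchmarkCase:
    """Assemble the full benchmark: target ensemble + predictor A targets,
    prior ensemble + predictor B observables, plus a per-observable check
    that every target value lies inside the prior ensemble's value range."""
    config = config or GeneratorConfig()
    target_ss = generate_ss_ensemble(
        config.propensity_target,
        config.n_frames,
        config.min_helix_run,
        rng=stream_rng(config.seed, "ss_target"),
    )
    prior_ss = generate_ss_ensemble(
        config.propensity_prior,
        config.n_frames,
        config.min_helix_run,
        rng=stream_rng(config.seed, "ss_prior"),
    )
    target_cs = predict_shifts_A(
        target_ss, config, rng=stream_rng(config.seed, "thermal_target")
    )
    prior_cs = predict_shifts_B(
        prior_ss,
        config,
        rng_thermal=stream_rng(config.seed, "thermal_prior"),
        rng_noise=stream_rng(config.seed, "pred_b"),
    )
    targets = make_target_set(target_cs, config)
    in_support = (prior_cs.values.min(axis=0) <= targets.values) & (
        targets.values <= prior_cs.values.max(axis=0)
    )
    return BenchmarkCase(
        target_cs=target_cs,
        target_ss=target_ss,
        prior_cs=prior_cs,
        prior_ss=prior_ss,
        targets=targets,
        truth=config,
        target_in_support=in_support,
    )


def rg_proxy(
    ss: SSMatrix,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    c0: float = 2.5,
    c1: float = 1.0,
) -> np.ndarray:
    """Scalar per-frame compactness proxy: c0 - c1 * (frame helix fraction)
    + noise.  Helical frames are more compact, so the proxy decreases with
    helicity.  Used only to illustrate that an indirect observable is a
    poor cross-validation signal."""
    if rng is None:
        if seed is None:
            raise ValidationError("provide either rng or seed")
        rng = stream_rng(seed, "rg")
    frac = (ss.codes == "H").mean(axis=1)
    noise = rng.normal(0.0, noise_sd, size=ss.n_frames) if noise_sd > 0 else 0.0
    return c0 - c1 * frac + noise
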