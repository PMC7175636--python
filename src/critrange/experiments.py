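"""Config-driven experiment runner, fixtures and verification suites.

Every experiment takes a schema-validated config, runs deterministically
under its master seed, and writes a tidy CSV (one row per grid point, with
estimate, standard error and censoring bracket) plus a JSON metadata file
echoing the fully resolved config.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrete import (BRWSpec, OffspringLaw, OPRealization, OPSpec,
                       gw_exact_survival, gw_laplace_experiment,
                       gw_survival_experiment, gw_yaglom_experiment)
from .graphical import (ContactSpec, GraphicalRecord, SimCaps, VoterSpec)
from .kernels import uniform_box_kernel
from .observables import (ModulusConfig, estimate_survival_prob,
                          modulus_tail_experiment, one_arm, spatial_moment)
from .ancestry import check_ar_axioms
from .sbm import (SBMParams, escape_probability, laplace_integrated_mass,
                  solve_vd0)
from .seeding import child_seed

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment",
           "make_fixture", "verify_all", "trajectory_to_csv", "build_spec"]

_EXPERIMENTS = ("survival", "one_arm", "modulus", "yaglom", "gw_survival",
                "laplace", "spatial_moment", "ar_axioms", "vd0", "escape")

_LAWS = {
    "binary": OffspringLaw.binary_critical,
    "delta1": lambda: OffspringLaw.delta(1),
    "variance_two": OffspringLaw.variance_two,
}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Validated experiment description.

    ``model`` holds the model family and its parameters, e.g.
    {"family": "vm", "d": 2, "L": 1} or {"family": "cp", "d": 2, "L": 1,
    "lam": 1.2} or {"family": "brw", "law": "binary", "d": 2, "L": 1}.
    """

    experiment: str
    seed: int = 0
    reps: int = 1000
    model: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    caps: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise ConfigError(f"experiment: unknown name {self.experiment!r}; "
                              f"choose one of {_EXPERIMENTS}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed: must be a nonnegative integer")
        if not isinstance(self.reps, int) or self.reps < 1:
            raise ConfigError("reps: must be a positive integer")
        fam = self.model.get("family")
        if self.experiment in ("survival", "one_arm", "modulus",
                               "spatial_moment", "ar_axioms"):
            if fam not in ("vm", "cp", "op", "brw"):
                raise ConfigError("model.family: must be vm, cp, op or brw")
            for key in ("d", "L"):
                val = self.model.get(key)
                if not isinstance(val, int) or val < 1:
                    raise ConfigError(f"model.{key}: must be a positive integer")
            if fam == "cp" and not isinstance(self.model.get("lam"), (int, float)):
                raise ConfigError("model.lam: required for the contact process")
            if fam == "op" and not isinstance(self.model.get("p"), (int, float)):
                raise ConfigError("model.p: required for oriented percolation")
            if fam == "brw" and self.model.get("law") not in _LAWS:
                raise ConfigError(f"model.law: must be one of {sorted(_LAWS)}")
        if self.experiment in ("gw_survival", "yaglom", "laplace"):
            if self.model.get("law") not in _LAWS:
                raise ConfigError(f"model.law: must be one of {sorted(_LAWS)}")

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        known = {"experiment", "seed", "reps", "model", "params", "caps"}
        extra = set(obj) - known
        if extra:
            raise ConfigError(f"{sorted(extra)[0]}: unknown config field")
        return cls(**obj)


def build_spec(model: dict):
    fam = model["family"]
    kernel = uniform_box_kernel(model["d"], model["L"])
    if fam == "vm":
        return VoterSpec(kernel)
    if fam == "cp":
        return ContactSpec(kernel, float(model["lam"]))
    if fam == "op":
        return OPSpec(kernel, float(model["p"]))
    if fam == "brw":
        return BRWSpec(_LAWS[model["law"]](), kernel)
    raise ConfigError(f"model.family: unknown family {fam!r}")


def _caps(cfg: ExperimentConfig):
    if not cfg.caps:
        return None
    return SimCaps(**cfg.caps)


def _rows(cfg: ExperimentConfig):
    p = cfg.params
    if cfg.experiment == "gw_survival":
        law = _LAWS[cfg.model["law"]]()
        n = int(p.get("n", 100))
        est = gw_survival_experiment(law, n, cfg.reps, seed=child_seed(cfg.seed, "gw_survival"))
        return [{"n": n, "estimate": est.value, "se": est.se,
                 "exact_recursion": n * gw_exact_survival(law, n),
                 "censored_lo": est.value, "censored_hi": est.value}]
    if cfg.experiment == "yaglom":
        law = _LAWS[cfg.model["law"]]()
        n = int(p.get("n", 100))
        est, _ = gw_yaglom_experiment(law, n, cfg.reps,
                                      seed=child_seed(cfg.seed, "yaglom"),
                                      min_survivors=p.get("min_survivors"))
        return [{"n": n, "estimate": est.value, "se": est.se,
                 "survivors": est.meta["survivors"],
                 "censored_lo": est.value, "censored_hi": est.value}]
    if cfg.experiment == "laplace":
        law = _LAWS[cfg.model["law"]]()
        n = int(p.get("n", 100))
        rows = []
        for lam in p.get("lams", [0.5, 1.0, 2.0]):
            est = gw_laplace_experiment(law, lam, n, cfg.reps,
                                        seed=child_seed(cfg.seed, f"laplace-{lam}"))
            closed = laplace_integrated_mass(SBMParams(law.gamma, 1.0), lam)
            rows.append({"n": n, "lambda": lam, "estimate": est.value,
                         "se": est.se, "closed_form": closed,
                         "censored_lo": est.value, "censored_hi": est.value})
        return rows
    if cfg.experiment == "survival":
        spec = build_spec(cfg.model)
        rows = []
        for t in p.get("times", [1.0, 2.0, 5.0]):
            est = estimate_survival_prob(spec, float(t), cfg.reps, cfg.seed,
                                         caps=_caps(cfg))
            rows.append({"t": t, "estimate": est.value, "se": est.se,
                         "censored_lo": est.lo, "censored_hi": est.hi,
                         "censored_fraction": est.censored_fraction})
        return rows
    if cfg.experiment == "one_arm":
        spec = build_spec(cfg.model)
        grid = p.get("radii", [5.0, 10.0])
        ests = one_arm(spec, grid, cfg.reps, cfg.seed, caps=_caps(cfg),
                       horizon=p.get("horizon"))
        return [{"r": r, "estimate": e.value, "se": e.se,
                 "r2_eta": r * r * e.value,
                 "censored_lo": e.lo, "censored_hi": e.hi,
                 "censored_fraction": e.censored_fraction}
                for r, e in sorted(ests.items())]
    if cfg.experiment == "spatial_moment":
        spec = build_spec(cfg.model)
        rows = []
        for t in p.get("times", [4.0]):
            est = spatial_moment(spec, float(t), float(p.get("p", 2.0)),
                                 cfg.reps, cfg.seed, caps=_caps(cfg))
            rows.append({"t": t, "p": p.get("p", 2.0), "estimate": est.value,
                         "se": est.se, "normalized": est.meta["normalized"],
                         "censored_lo": est.lo, "censored_hi": est.hi})
        return rows
    if cfg.experiment == "ar_axioms":
        spec = build_spec(cfg.model)
        horizon = float(p.get("horizon", 3.0))
        rows = []
        for rep in range(cfg.reps):
            rng = np.random.default_rng(child_seed(cfg.seed, "ar_axioms", rep))
            sim = spec.sample(horizon, rng, caps=_caps(cfg), keep_record=True)
            sys = spec.system(sim)
            rep_report = check_ar_axioms(sys, n_triples=int(p.get("n_triples", 100)),
                                         rng=rng)
            rows.append({"replicate": rep, "passed": rep_report.passed,
                         "violations": sum(len(w) for w in rep_report.witnesses.values())})
        return rows
    if cfg.experiment == "vd0":
        rows = []
        for d in p.get("dims", [1, 2, 3, 4]):
            sol = solve_vd0(int(d), tol=float(p.get("tol", 1e-6)))
            rows.append({"d": d, "v_d0": sol.vd0, "err_bound": sol.vd0_err,
                         "blow_up_radius": sol.blow_up_radius})
        return rows
    if cfg.experiment == "escape":
        kernel = uniform_box_kernel(cfg.model.get("d", 3), cfg.model.get("L", 1))
        four = escape_probability(kernel, "fourier")
        mc = escape_probability(kernel, "monte_carlo", seed=cfg.seed,
                                n_walks=cfg.reps)
        return [{"d": kernel.d, "L": kernel.L, "fourier": four["value"],
                 "monte_carlo": mc["value"], "mc_se": mc["se"],
                 "mc_tail_bound": mc["tail_bound"]}]
    if cfg.experiment == "modulus":
        spec = build_spec(cfg.model)
        cfg_mod = ModulusConfig(alpha=float(p.get("alpha", 0.25)),
                                beta=float(p.get("beta", 1.0)),
                                p=float(p.get("p", 40.0)),
                                kappa=float(p.get("kappa", 30.0)))
        table, slopes = modulus_tail_experiment(
            spec, p.get("n_grid", [16, 64]), p.get("rho_grid", [0.1, 0.3, 0.6]),
            cfg_mod, float(p.get("C", 1.0)), cfg.reps, cfg.seed, caps=_caps(cfg))
        table = table.copy()
        table["slope"] = table["n"].map(slopes)
        return table.to_dict("records")
    raise ConfigError(f"experiment: unhandled {cfg.experiment!r}")


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Run one experiment; write <experiment>.csv and <experiment>.meta.json.

    Deterministic for a fixed config: rerunning writes byte-identical CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rows = _rows(cfg)
    frame = pd.DataFrame(rows)
    for col in ("model", "seed", "reps"):
        frame[col] = {"model": json.dumps(cfg.model, sort_keys=True),
                      "seed": cfg.seed, "reps": cfg.reps}[col]
    csv_path = out_dir / f"{cfg.experiment}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.12g")
    meta = {"config": asdict(cfg), "version": __version__,
            "wall_time_s": time.time() - t0, "rows": len(frame)}
    meta_path = out_dir / f"{cfg.experiment}.meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {"csv": str(csv_path), "meta": str(meta_path), "frame": frame}


def trajectory_to_csv(traj, path):
    """Write (jump_time, occupied_sites) rows; sites are semicolon-joined
    comma-separated coordinates."""
    rows = [{"jump_time": 0.0,
             "occupied_sites": ";".join(",".join(map(str, s))
                                        for s in sorted(traj.set_at(0)))}]
    for t in traj.jump_times:
        occ = sorted(traj.set_at(t))
        rows.append({"jump_time": t,
                     "occupied_sites": ";".join(",".join(map(str, s)) for s in occ)})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# hand-traceable fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str):
    """Named deterministic fixtures used across the unit tests.

    voter_single_arrow: one arrow o -> +1 at time 0.3 on [0, 1] (d = 1).
    voter_two_arrow: arrows into o from +1 at 0.3 and into +1 from +2 at
    0.7 (the dual of (1, o) jumps to +1 at backward time 0.7).
    cp_recovery_arrow: recovery at (0.9, o), infection arrow o -> +1 at
    0.4, so T_0.5 = {o, +1} and T_1.0 = {+1}.
    op_three_gen: a 3-generation d = 1 cluster with two distinct occupied
    paths from (0, o) to (3, +1).
    """
    if name == "voter_single_arrow":
        return GraphicalRecord(model="voter", t_max=1.0,
                               arrows=[(0.3, (1,), (0,))], complete=True)
    if name == "voter_two_arrow":
        return GraphicalRecord(model="voter", t_max=1.0,
                               arrows=[(0.3, (0,), (1,)), (0.7, (1,), (2,))],
                               complete=True)
    if name == "cp_recovery_arrow":
        return GraphicalRecord(model="contact", t_max=1.0,
                               arrows=[(0.4, (1,), (0,))],
                               recoveries=[(0.9, (0,))], complete=True)
    if name == "op_three_gen":
        generations = [frozenset({(0,)}), frozenset({(-1,), (1,)}),
                       frozenset({(0,)}), frozenset({(1,)})]
        children = [{(0,): ((-1,), (1,))},
                    {(-1,): ((0,),), (1,): ((0,),)},
                    {(0,): ((1,),)}]
        return OPRealization(p=1.0, d=1, generations=generations,
                             children=children, n_max=3)
    raise ValueError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# verification suites
# ---------------------------------------------------------------------------

def verify_all(level: str = "quick", seed: int = 1, out_dir=None) -> dict:
    """Run the verification battery; 'quick' covers the fast checks, 'full'
    adds the Galton-Watson canonical-measure runs at their headline sizes
    and the scaled-down one-arm table."""
    if level not in ("quick", "full"):
        raise ValueError("level must be 'quick' or 'full'")
    checks = {}

    # Hausdorff empty-set convention
    from .observables import hausdorff
    checks["hausdorff_empty"] = {
        "value": hausdorff([], [(0.0,)]), "expect": 1.0,
        "pass": hausdorff([], [(0.0,)]) == 1.0}

    # voter mass martingale at t = 5, d = 2
    reps = 20000 if level == "full" else 4000
    spec = VoterSpec(uniform_box_kernel(2, 1))
    rng = np.random.default_rng(child_seed(seed, "verify-mass"))
    sizes = np.array([spec.simulate_fast(5.0, rng, eval_times=[5.0])["eval_sizes"][0]
                      for _ in range(reps)], dtype=float)
    mean, se = sizes.mean(), sizes.std(ddof=1) / math.sqrt(reps)
    checks["voter_mass"] = {"value": mean, "se": se, "expect": 1.0,
                            "pass": abs(mean - 1.0) <= 3 * se}

    # closed-form suite
    sol = solve_vd0(2, tol=1e-6)
    checks["vd0_d2"] = {"value": sol.vd0, "err_bound": sol.vd0_err,
                        "pass": sol.vd0_err < 1e-6}

    if level == "full":
        law = OffspringLaw.binary_critical()
        est = gw_survival_experiment(law, 100, 500_000,
                                     seed=child_seed(seed, "verify-gw"))
        exact = 100 * gw_exact_survival(law, 100)
        checks["gw_survival"] = {"value": est.value, "se": est.se,
                                 "exact": exact,
                                 "pass": abs(est.value - exact) <= 3 * est.se}
        yag, _ = gw_yaglom_experiment(law, 100, 200_000,
                                      seed=child_seed(seed, "verify-yag"),
                                      min_survivors=10_000)
        checks["gw_yaglom"] = {"value": yag.value, "se": yag.se, "expect": 2.0,
                               "pass": abs(yag.value - exact) <= 3 * yag.se + 0.02}
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_, bool)):
            return bool(obj)
        return obj

    summary = _plain({"level": level, "seed": seed,
                      "passed": all(bool(c.get("pass", True))
                                    for c in checks.values()),
                      "checks": checks})
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "verify.json").write_text(json.dumps(summary, indent=2))
    return summary
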