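"""Config-driven parameter sweeps over ensembles of noisy gradients.

An :class:`ExperimentConfig` holds a base simulation setup plus a
``sweep`` mapping of dotted field paths to value lists; the sweep runs
the full cross product and emits one tidy row per (sweep point, target
position). Presets encode the study designs this package is built
around: cell-area-CV sweeps, cell-size scaling, readout along the
domain for several decay exponents, production-only noise, source
boundary-condition comparisons, and source-strength sweeps — each at a
desk-scale replicate count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from morphograd.kinetics import KineticSpec, SourceBoundarySpec, default_kinetics
from morphograd.readout import EnsembleConfig, positional_error, run_ensemble
from morphograd.tissue_domain import AreaDistributionSpec

__all__ = [
    "ExperimentConfig",
    "run_sweep",
    "compare_decay_orders",
    "PRESETS",
    "preset",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Base simulation setup plus sweep axes.

    ``sweep`` maps dotted field paths (``"kinetics.n"``,
    ``"area.cv_A"``, ``"source.cv_j0"``, ``"production_factor"``,
    ``"Lp_over_delta"``, ``"area.mu_delta"``, ...) to lists of values;
    the cross product over all axes is simulated. ``production_factor``
    scales the mean morphogen supply of whichever source mode is
    active (mu_p, mu_j0 or mu_C0); at defaults it equals the
    dimensionless mean production ``p / (d * C_ref)``.
    """

    kinetics: KineticSpec = field(default_factory=default_kinetics)
    area: AreaDistributionSpec = field(default_factory=AreaDistributionSpec)
    source: SourceBoundarySpec = field(default_factory=SourceBoundarySpec)
    Ls_over_delta: float = 5.0
    Lp_over_delta: float = 200.0
    x_targets_over_delta: tuple = (5.0, 75.0)
    x_targets_unit: str = "delta"  # "delta" (multiples of mu_delta) | "Lp_fraction" | "um"
    production_factor: float = 1.0
    n_replicates: int = 300
    seed: int = 0
    sweep: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if len(self.x_targets_over_delta) == 0:
            raise ValueError("at least one readout target is required")
        if self.x_targets_unit not in ("delta", "Lp_fraction", "um"):
            raise ValueError(f"unknown x_targets_unit {self.x_targets_unit!r}")
        for key, values in self.sweep.items():
            if not isinstance(values, (list, tuple)) or len(values) == 0:
                raise ValueError(f"sweep axis {key!r} must be a non-empty list")
            self._validate_key(key)

    def _validate_key(self, key: str) -> None:
        if "." in key:
            head, attr = key.split(".", 1)
            if head not in ("kinetics", "area", "source") or "." in attr or not hasattr(getattr(self, head), attr):
                raise ValueError(f"unknown sweep key {key!r}")
        elif key not in ("production_factor", "Lp_over_delta", "Ls_over_delta", "n_replicates"):
            raise ValueError(f"unknown sweep key {key!r}")

    # -- config (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "kinetics": enc(self.kinetics),
            "area": enc(self.area),
            "source": enc(self.source),
            "Ls_over_delta": self.Ls_over_delta,
            "Lp_over_delta": self.Lp_over_delta,
            "x_targets_over_delta": list(self.x_targets_over_delta),
            "x_targets_unit": self.x_targets_unit,
            "production_factor": self.production_factor,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "sweep": {k: list(v) for k, v in self.sweep.items()},
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "ExperimentConfig":
        rec = dict(rec)
        kin = rec.pop("kinetics", None)
        area = rec.pop("area", None)
        src = rec.pop("source", None)
        kwargs = dict(rec)
        kwargs["kinetics"] = KineticSpec(**kin) if kin else default_kinetics()
        kwargs["area"] = AreaDistributionSpec(**area) if area else AreaDistributionSpec()
        kwargs["source"] = SourceBoundarySpec(**src) if src else SourceBoundarySpec()
        if "x_targets_over_delta" in kwargs:
            kwargs["x_targets_over_delta"] = tuple(kwargs["x_targets_over_delta"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- sweep machinery -----------------------------------------------------

    def _apply_override(self, key: str, value) -> "ExperimentConfig":
        if "." in key:
            head, attr = key.split(".", 1)
            if head not in ("kinetics", "area", "source") or "." in attr:
                raise ValueError(f"unknown sweep key {key!r}")
            sub = getattr(self, head)
            if not hasattr(sub, attr):
                raise ValueError(f"unknown sweep key {key!r}")
            return replace(self, **{head: replace(sub, **{attr: value})})
        if key in ("production_factor", "Lp_over_delta", "Ls_over_delta", "n_replicates"):
            return replace(self, **{key: value})
        raise ValueError(f"unknown sweep key {key!r}")

    def sweep_points(self) -> list["ExperimentConfig"]:
        """Cross product of all sweep axes as fully-resolved configs."""
        keys = sorted(self.sweep)
        configs = [replace(self, sweep={})]
        for key in keys:
            configs = [
                cfg._apply_override(key, v) for cfg in configs for v in self.sweep[key]
            ]
        return configs

    # -- derived simulation inputs -------------------------------------------

    def ensemble_config(self) -> EnsembleConfig:
        kin = self.kinetics
        src = self.source
        if self.production_factor != 1.0:
            f = self.production_factor
            if src.mode == "source-domain":
                kin = replace(kin, mu_p=kin.mu_p * f)
            elif src.mode == "flux":
                src = replace(src, mu_j0=src.mu_j0 * f)
            else:
                src = replace(src, mu_C0=src.mu_C0 * f)
        return EnsembleConfig(
            kinetics=kin,
            area=self.area,
            source=src,
            Ls_over_delta=self.Ls_over_delta,
            Lp_over_delta=self.Lp_over_delta,
        )

    def x_targets(self) -> list[float]:
        """Target readout positions in µm."""
        if self.x_targets_unit == "Lp_fraction":
            lp = self.Lp_over_delta * self.area.mu_delta
            return [f * lp for f in self.x_targets_over_delta]
        if self.x_targets_unit == "um":
            return [float(f) for f in self.x_targets_over_delta]
        return [f * self.area.mu_delta for f in self.x_targets_over_delta]


def _point_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_sweep(
    config: ExperimentConfig,
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every sweep point and return a tidy results table.

    One row per (sweep point, readout target): decay exponent, noise
    levels, source mode, mean production, target position and the
    measured positional error with its bootstrap SE, plus censoring
    and solver-failure counts. Deterministic for a given master seed;
    each sweep point runs on an independently derived substream.
    """
    points = config.sweep_points()
    children = np.random.SeedSequence(config.seed).spawn(len(points))
    rows = []
    for i, (pt, child) in enumerate(zip(points, children)):
        ens_cfg = pt.ensemble_config()
        targets = pt.x_targets()
        pt_seed = _point_seed(child)
        ensembles = run_ensemble(
            ens_cfg, targets, n_replicates=pt.n_replicates, seed=pt_seed, n_jobs=n_jobs
        )
        boot_rng = np.random.default_rng(child.spawn(1)[0])
        mu_delta = pt.area.mu_delta
        for x_t, ens in ensembles.items():
            try:
                summary = positional_error(ens, rng=boot_rng)
                sigma_x, se, mu_x = summary.sigma_x, summary.sigma_x_se, summary.mu_x
                n_used = summary.n_used
            except ValueError:  # (almost) fully censored ensemble
                sigma_x = se = mu_x = np.nan
                n_used = ens.uncensored.size
            rows.append(
                {
                    "n": pt.kinetics.n,
                    "cv_p": pt.kinetics.cv_p,
                    "cv_d": pt.kinetics.cv_d,
                    "cv_D": pt.kinetics.cv_D,
                    "cv_A": pt.area.cv_A,
                    "cv_j0": pt.source.cv_j0,
                    "cv_C0": pt.source.cv_C0,
                    "mu_delta": mu_delta,
                    "bc_mode": pt.source.mode,
                    "mean_production": pt.production_factor,
                    "Lp_over_delta": pt.Lp_over_delta,
                    "x_target_over_delta": x_t / mu_delta,
                    "mu_x": mu_x,
                    "sigma_x": sigma_x,
                    "sigma_x_over_delta": sigma_x / mu_delta,
                    "se_over_delta": se / mu_delta,
                    "n_used": n_used,
                    "n_censored": ens.n_censored,
                    "n_failed": ens.n_failed,
                    "unreliable": ens.unreliable,
                    "seed": pt_seed,
                }
            )
        if progress:
            print(f"[{i + 1}/{len(points)}] n={pt.kinetics.n} done", flush=True)
    return pd.DataFrame(rows)


_PAIRING_COLUMNS = [
    "cv_p",
    "cv_d",
    "cv_D",
    "cv_A",
    "cv_j0",
    "cv_C0",
    "mu_delta",
    "bc_mode",
    "mean_production",
    "Lp_over_delta",
    "x_target_over_delta",
]


def compare_decay_orders(results: pd.DataFrame, x_targets=None) -> pd.DataFrame:
    """Difference in positional error between non-linear (n > 1) and
    linear (n = 1) decay at matched conditions.

    Returns rows of ``delta_sigma_over_delta = (sigma_x[n] -
    sigma_x[1]) / mu_delta`` with standard errors propagated in
    quadrature. Raises if a non-linear row has no matching n = 1 row.
    """
    if x_targets is not None:
        results = results[results["x_target_over_delta"].isin(list(x_targets))]
    base = results[results["n"] == 1]
    others = results[results["n"] > 1]
    if base.empty or others.empty:
        raise ValueError("comparison requires both n = 1 and n > 1 rows")
    keys = [c for c in _PAIRING_COLUMNS if c in results.columns]
    merged = others.merge(base, on=keys, suffixes=("", "_lin"), how="left")
    if merged["sigma_x_over_delta_lin"].isna().any() and not merged.empty:
        missing = merged[merged["sigma_x_over_delta_lin"].isna()]
        raise ValueError(
            f"{len(missing)} non-linear rows have no matching n = 1 row at the same conditions"
        )
    out = merged[keys + ["n"]].copy()
    out["delta_sigma_over_delta"] = (
        merged["sigma_x_over_delta"] - merged["sigma_x_over_delta_lin"]
    )
    out["se_over_delta"] = np.sqrt(
        merged["se_over_delta"] ** 2 + merged["se_over_delta_lin"] ** 2
    )
    return out


# ---------------------------------------------------------------------------
# presets: scaled-down versions of the study's sweep designs
# ---------------------------------------------------------------------------

_ALONG_DOMAIN = (2.0, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0, 190.0)
_CV_AXIS = [0.0, 0.1, 0.2, 0.3, 0.5, 1.0]
_PRODUCTION_AXIS = [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0]


def _base(**kwargs) -> ExperimentConfig:
    return ExperimentConfig(**kwargs)


def _preset_fig3a(replicates: int) -> ExperimentConfig:
    return _base(
        n_replicates=replicates,
        x_targets_over_delta=(5.0, 75.0, 150.0),
        sweep={"area.cv_A": [0.0, 0.3, 0.5, 0.7, 0.9], "kinetics.n": [1.0, 2.0, 4.0]},
    )


def _preset_fig3b(replicates: int) -> ExperimentConfig:
    return _base(
        n_replicates=replicates,
        Lp_over_delta=100.0,
        x_targets_over_delta=(50.0,),
        x_targets_unit="um",
        sweep={"area.mu_delta": [1.25, 2.5, 5.0, 10.0], "kinetics.n": [1.0, 2.0]},
    )


def _preset_fig3c(replicates: int) -> ExperimentConfig:
    return _base(
        n_replicates=replicates,
        x_targets_over_delta=_ALONG_DOMAIN,
        sweep={"kinetics.n": [1.0, 2.0, 3.0, 4.0]},
    )


def _preset_fig3d(replicates: int) -> ExperimentConfig:
    return _base(
        kinetics=default_kinetics(cv_d=0.0, cv_D=0.0),
        n_replicates=replicates,
        x_targets_over_delta=_ALONG_DOMAIN,
        sweep={"kinetics.n": [1.0, 2.0, 3.0, 4.0]},
    )


def _preset_fig3e(replicates: int) -> ExperimentConfig:
    # differences are computed from the fig3c table via compare_decay_orders
    return _preset_fig3c(replicates)


def _preset_fig3f(replicates: int) -> ExperimentConfig:
    return _base(
        n_replicates=replicates,
        x_targets_unit="Lp_fraction",
        x_targets_over_delta=(0.1, 0.25, 0.5, 0.75, 0.9, 0.95),
        sweep={"Lp_over_delta": [50.0, 100.0, 150.0, 200.0], "kinetics.n": [1.0, 2.0]},
    )


def _bc_cv_preset(mode: str, cv_key: str, replicates: int) -> ExperimentConfig:
    return _base(
        source=SourceBoundarySpec(mode=mode),
        n_replicates=replicates,
        x_targets_over_delta=(5.0, 75.0),
        sweep={cv_key: _CV_AXIS, "kinetics.n": [1.0, 2.0, 4.0]},
    )


def _production_preset(mode: str, target: float, replicates: int) -> ExperimentConfig:
    return _base(
        source=SourceBoundarySpec(mode=mode),
        n_replicates=replicates,
        x_targets_over_delta=(target,),
        sweep={"production_factor": _PRODUCTION_AXIS, "kinetics.n": [1.0, 2.0, 4.0]},
    )


PRESETS = {
    "fig3a": _preset_fig3a,
    "fig3b": _preset_fig3b,
    "fig3c": _preset_fig3c,
    "fig3d": _preset_fig3d,
    "fig3e": _preset_fig3e,
    "fig3f": _preset_fig3f,
    "fig4d": lambda r: _bc_cv_preset("source-domain", "kinetics.cv_p", r),
    "fig4e": lambda r: _bc_cv_preset("flux", "source.cv_j0", r),
    "fig4f": lambda r: _bc_cv_preset("dirichlet", "source.cv_C0", r),
    "fig5a": lambda r: _production_preset("source-domain", 5.0, r),
    "fig5b": lambda r: _production_preset("flux", 5.0, r),
    "fig5c": lambda r: _production_preset("dirichlet", 5.0, r),
    "fig5d": lambda r: _production_preset("source-domain", 150.0, r),
    "fig5e": lambda r: _production_preset("flux", 150.0, r),
    "fig5f": lambda r: _production_preset("dirichlet", 150.0, r),
}


def preset(name: str, replicates: int = 300, seed: int = 0) -> ExperimentConfig:
    """Build a named preset configuration at the given replicate count."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name](replicates)
    return replace(cfg, seed=seed)
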