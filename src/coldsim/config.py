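"""YAML configuration loading, run manifests, and fixture generation."""

from __future__ import annotations

import dataclasses
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import DEFAULT_ANCHORS, QuantileAnchors, build_synthetic_cohort
from .dose_response import HillParams, LogisticParams
from .field import FieldParams, check_stability
from .model import SimulationConfig

__all__ = ["load_config", "dump_config", "write_manifest", "make_fixture"]


class ConfigFileError(ValueError):
    pass


_TOP_KEYS = {"simulation", "evasion", "hill", "field", "anchors"}


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigFileError(f"unknown keys in '{section}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> tuple[SimulationConfig, QuantileAnchors]:
    """Load a simulation configuration (plus cohort anchors) from YAML.

    An empty or missing file yields the full baseline defaults.  Unknown
    keys are rejected, and unstable PDE parameter sets abort at startup
    citing the violated bound.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigFileError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigFileError(f"unknown top-level config sections: {sorted(unknown)}")

    logistic = _build_section(LogisticParams, raw.get("evasion", {}) or {}, "evasion")
    hill = _build_section(HillParams, raw.get("hill", {}) or {}, "hill")
    fieldp = _build_section(FieldParams, raw.get("field", {}) or {}, "field")
    rep = check_stability(fieldp)
    if not rep.stable:
        raise ConfigFileError(
            "unstable PDE parameters: combined factor "
            f"{rep.combined:.3f} must be <= 1 and CFL ratio {rep.cfl_ratio:.3f} "
            "must be <= 0.25 and decay factor "
            f"{rep.decay_factor:.3f} must be < 1"
        )

    sim_raw = dict(raw.get("simulation", {}) or {})
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_raw) - sim_fields
    if unknown:
        raise ConfigFileError(f"unknown keys in 'simulation': {sorted(unknown)}")
    config = SimulationConfig(logistic=logistic, hill=hill, field=fieldp, **sim_raw)

    anchors = DEFAULT_ANCHORS
    if "anchors" in raw and raw["anchors"]:
        a = raw["anchors"]
        anchors = QuantileAnchors(probs=tuple(a["probs"]), values=tuple(a["values"]))
    return config, anchors


def dump_config(config: SimulationConfig) -> dict:
    """Nested plain-dict form of a configuration (YAML-serialisable)."""
    d = dataclasses.asdict(config)
    return {
        "simulation": {
            k: v for k, v in d.items() if k not in ("logistic", "hill", "field")
        },
        "evasion": d["logistic"],
        "hill": d["hill"],
        "field": d["field"],
    }


def write_manifest(
    out_dir: str | Path,
    config: SimulationConfig,
    arm_specs: list | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a run manifest sufficient to re-run any replicate bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "coldsim_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": dump_config(config),
        "seed_scheme": "sha256('{base_seed}:{arm_id}:{replicate_index}') mod 2^31",
        "arms": [
            {"name": s.name, "n_replicates": s.n_replicates, "max_steps": s.max_steps}
            for s in (arm_specs or [])
        ],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path = ".") -> list[Path]:
    """Write small deterministic fixture files used by the test-suite and docs.

    Kinds: ``tiny_grid`` (a 10x10 two-arm config), ``impulse_field`` (a
    single-impulse concentration CSV), ``sanctuary_toy`` (a hand-built
    snapshot with one qualifying 4-cell component and one sub-threshold
    3-cell component), ``cohort_554`` (a 554-sample synthetic cohort CSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "cohort_554":
        cohort = build_synthetic_cohort(n=554, rng_seed=seed)
        p = out_dir / "cohort_554.csv"
        p.write_text("tpm\n" + "\n".join(f"{v:.6f}" for v in cohort.samples) + "\n")
        written.append(p)
    elif kind == "impulse_field":
        grid = np.zeros((10, 10))
        grid[5, 5] = 1.0
        p = out_dir / "impulse_field.csv"
        np.savetxt(p, grid, fmt="%.6f", delimiter=",")
        written.append(p)
    elif kind == "tiny_grid":
        p = out_dir / "tiny_grid.yaml"
        p.write_text(
            yaml.safe_dump(
                {
                    "simulation": {
                        "grid_l": 10,
                        "grid_w": 10,
                        "n_tumour0": 20,
                        "n_immune0": 10,
                        "max_steps": 50,
                        "base_seed": int(seed),
                    }
                }
            )
        )
        written.append(p)
    elif kind == "sanctuary_toy":
        written.extend(_write_sanctuary_toy(out_dir))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


def _write_sanctuary_toy(out_dir: Path) -> list[Path]:
    from .testing import sanctuary_toy_snapshot

    snap = sanctuary_toy_snapshot()
    pt = out_dir / "sanctuary_toy_tumour.csv"
    snap.tumour.to_csv(pt, index=False)
    pi = out_dir / "sanctuary_toy_immune.csv"
    snap.immune.to_csv(pi, index=False)
    pf = out_dir / "sanctuary_toy_field.csv"
    np.savetxt(pf, snap.conc, fmt="%.4f", delimiter=",")
    return [pt, pi, pf]
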