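"""Synthetic multi-cell datasets and toy cohort tables.

Emulates whole-cell recordings from transfected HEK293T cells: per-cell
gating-parameter variability (independent truncated-normal perturbations
whose spreads are derived from the published per-group mean +/- SEM values
via SD = SEM * sqrt(n)), additive Gaussian current noise, optional linear
leak with P/5 subtraction, and a moving-average filter standing in for the
5-kHz low-pass of the acquisition chain (20-kHz sampling).

Default group sizes are the study's: 19 WT, 11 M1852T, 9 T1596I cells.
Everything is deterministic under a master seed; per-cell seeds are spawned
from it with ``numpy.random.SeedSequence`` and recorded in the dataset
manifest.

The cohort generator emits toy variant / participant tables with the
structure of the diabetic-neuropathy screen: 111 painful vs 78 painless
participants, 12 rare variants carried by 10 participants, all in the
painful group (one participant carries four variants, one variant is shared
by two participants).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .gating import GatingParameterSet, load_params
from .io import write_sweeps
from .protocols import PROTOCOL_FACTORIES, Sweep, SweepSet, simulate
from .variants import PREDICTORS

__all__ = [
    "CellRecord",
    "NoiseConfig",
    "DatasetConfig",
    "CohortSpec",
    "default_spread",
    "sample_cell",
    "corrupt",
    "generate_dataset",
    "generate_cohort",
]

# Cell-level SDs derived from published mean +/- SEM per panel:
# SD = SEM * sqrt(n), with the per-panel n. Fields not listed are fixed.
_SEM_N = {
    "WT": {
        "act_v_half": (1.3, 19), "act_k": (0.3, 19),
        "fast_v_half": (1.4, 18), "fast_k": (0.2, 18),
        "slow_v_half": (2.8, 12), "slow_k": (0.5, 12),
        "tau_h_depol": (0.1, 19), "tau_h_hyper": (16.7, 14),
    },
    "M1852T": {
        "act_v_half": (1.3, 11), "act_k": (0.5, 11),
        "fast_v_half": (3.0, 11), "fast_k": (0.3, 11),
        "slow_v_half": (3.8, 8), "slow_k": (0.8, 8),
        "tau_h_depol": (0.3, 11), "tau_h_hyper": (21.8, 9),
    },
    "T1596I": {
        "act_v_half": (2.4, 9), "act_k": (0.6, 9),
        "fast_v_half": (2.2, 9), "fast_k": (0.3, 9),
        "slow_v_half": (2.4, 9), "slow_k": (0.7, 9),
        "tau_h_depol": (0.5, 9), "tau_h_hyper": (6.8, 8),
    },
}

DEFAULT_GROUP_SIZES = {"WT": 19, "M1852T": 11, "T1596I": 9}


def default_spread(label: str) -> dict[str, float]:
    """Per-field cell-level SD (SEM * sqrt(n)) for a packaged group."""
    table = _SEM_N[label.strip().upper() if label.upper() in _SEM_N else label]
    return {k: sem * np.sqrt(n) for k, (sem, n) in table.items()}


@dataclass
class CellRecord:
    """One synthetic cell: its sampled parameters and provenance."""

    cell_id: str
    group: str
    params: GatingParameterSet
    seed: int


@dataclass
class NoiseConfig:
    """Measurement model for :func:`corrupt`.

    ``filter_window`` is the moving-average length in samples emulating the
    5-kHz low-pass at 20-kHz sampling (rate / cutoff = 4 samples).
    """

    current_noise_sd: float = 10.0  # pA
    leak_conductance: float = 0.0  # nS, reversal at 0 mV
    enable_p5: bool = True
    filter_window: int = 4

    def __post_init__(self) -> None:
        if self.current_noise_sd < 0 or self.leak_conductance < 0:
            raise ValueError("noise sd and leak conductance must be >= 0")


def sample_cell(
    group_params: GatingParameterSet,
    spread: dict[str, float] | None,
    rng_seed: int,
    cell_id: str | None = None,
    max_tries: int = 1000,
) -> CellRecord:
    """Draw one cell's parameters around a group mean.

    Each field in ``spread`` is perturbed independently (normal, SD in the
    field's own units); a draw violating the parameter-set invariants is
    resampled.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    spread = spread or {}
    for _ in range(max_tries):
        changes = {
            name: getattr(group_params, name) + rng.normal(0.0, sd)
            for name, sd in spread.items()
        }
        try:
            params = group_params.replace(**changes)
        except ValueError:
            continue
        return CellRecord(
            cell_id=cell_id or f"{group_params.label}_cell",
            group=group_params.label,
            params=params,
            seed=int(rng_seed),
        )
    raise RuntimeError("could not sample a valid parameter set")


def corrupt(ss: SweepSet, noise: NoiseConfig, rng_seed: int) -> SweepSet:
    """Apply the measurement model to a noiseless SweepSet.

    Adds linear leak g_leak * (V - 0 mV) and Gaussian current noise, applies
    the moving-average filter, and (if enabled) performs a P/5 leak
    correction: five 1/5-amplitude replicas of the command (relative to
    holding) are synthesized after the test pulse, their summed response
    plus a scaled holding-trace baseline is subtracted, so the leak cancels
    in expectation while channel current is untouched.
    """
    rng = np.random.default_rng(rng_seed)
    g_leak = noise.leak_conductance
    sd = noise.current_noise_sd
    hold = ss.protocol.holding_mv

    def _filt(x):
        if noise.filter_window > 1:
            return uniform_filter1d(x, size=noise.filter_window, mode="nearest")
        return x

    new_sweeps = []
    for sw in ss.sweeps:
        raw = sw.current_pa + g_leak * sw.command_mv + rng.normal(0.0, sd, sw.current_pa.shape)
        corrected = _filt(raw)
        if noise.enable_p5 and ss.protocol.leak_sub == "p_over_n":
            n_sub = ss.protocol.leak_n
            sub_cmd = hold + (sw.command_mv - hold) / n_sub
            sub_sum = np.zeros_like(corrected)
            for _ in range(n_sub):
                sub = g_leak * sub_cmd + rng.normal(0.0, sd, sub_cmd.shape)
                sub_sum += _filt(sub)
            baseline_trace = g_leak * hold + rng.normal(0.0, sd, sub_cmd.shape)
            baseline = float(np.mean(_filt(baseline_trace)))
            corrected = corrected - sub_sum + (n_sub - 1) * baseline
        new_sweeps.append(
            Sweep(
                index=sw.index, value=sw.value, time_ms=sw.time_ms.copy(),
                command_mv=sw.command_mv.copy(), current_pa=corrected,
            )
        )
    meta = dict(ss.meta)
    meta.update(noiseless=False, noise=dataclasses.asdict(noise), seed=int(rng_seed))
    return SweepSet(protocol=ss.protocol, sweeps=new_sweeps, meta=meta)


@dataclass
class DatasetConfig:
    """Configuration for :func:`generate_dataset`."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    protocols: tuple[str, ...] = tuple(PROTOCOL_FACTORIES)
    noise: NoiseConfig | None = field(default_factory=NoiseConfig)
    spreads: dict[str, dict[str, float]] | None = None  # default: published SDs

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        if "protocols" in d:
            d["protocols"] = tuple(d["protocols"])
        return cls(**d)


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-cell 31-bit seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1, np.uint32)[0] % 2**31) for s in ss.spawn(n)]


def sample_cells(config: DatasetConfig, master_seed: int) -> list[CellRecord]:
    """Sample every cell of a dataset (deterministic under the master seed)."""
    cells = []
    n_total = sum(config.group_sizes.values())
    seeds = _spawn_seeds(master_seed, n_total)
    k = 0
    for group, n in config.group_sizes.items():
        base = load_params(group)
        spread = (
            config.spreads.get(group) if config.spreads is not None
            else default_spread(group)
        )
        for j in range(n):
            cells.append(
                sample_cell(base, spread, seeds[k], cell_id=f"{group}_{j:03d}")
            )
            k += 1
    return cells


def generate_dataset(
    config: DatasetConfig, out_dir: str | Path, master_seed: int = 0
) -> dict:
    """Simulate and write a full multi-cell dataset.

    Writes one CSV + JSON sidecar per cell x protocol under
    ``out_dir/cells/``, plus ``manifest.json`` listing groups, seeds and the
    configuration.  Byte-identical on re-run with the same master seed.
    """
    out_dir = Path(out_dir)
    (out_dir / "cells").mkdir(parents=True, exist_ok=True)
    cells = sample_cells(config, master_seed)
    manifest = {
        "master_seed": int(master_seed),
        "config": {
            "group_sizes": config.group_sizes,
            "protocols": list(config.protocols),
            "noise": dataclasses.asdict(config.noise) if config.noise else None,
        },
        "cells": [],
    }
    for cell in cells:
        cell_dir = out_dir / "cells" / cell.cell_id
        cell_dir.mkdir(exist_ok=True)
        for proto_name in config.protocols:
            proto = PROTOCOL_FACTORIES[proto_name]()
            ss = simulate(proto, cell.params, meta={"cell_id": cell.cell_id, "group": cell.group, "seed": cell.seed})
            if config.noise is not None:
                # per-protocol noise stream, deterministic in the cell seed
                proto_seed = (cell.seed * 131 + list(PROTOCOL_FACTORIES).index(proto_name)) % 2**31
                ss = corrupt(ss, config.noise, proto_seed)
            write_sweeps(ss, cell_dir / f"{proto_name}.csv")
        manifest["cells"].append(
            {
                "cell_id": cell.cell_id,
                "group": cell.group,
                "seed": cell.seed,
                "params": cell.params.to_dict(),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


@dataclass
class CohortSpec:
    """Structure of the toy case/control cohort and its variant table."""

    n_painful: int = 111
    n_painless: int = 78
    n_variants: int = 12
    n_carriers: int = 10
    carriers_in_painless: int = 0
    multi_variant_count: int = 4  # one carrier holds this many variants
    shared_variant_carriers: int = 2  # one variant appears in this many carriers
    n_literature_flagged: int = 5


def generate_cohort(
    spec: CohortSpec | None = None, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy variant table and participant/group table with the cohort's
    carrier structure.

    Returns ``(variants, participants)``: the variant table has MAFs in two
    databases, a literature-pain flag, four predictor calls and carrier
    ids; the participant table has one row per participant with its group.
    Deterministic given ``rng_seed``.
    """
    spec = spec or CohortSpec()
    if spec.n_carriers > 0 and spec.n_variants < spec.multi_variant_count:
        raise ValueError("fewer variants than the multi-variant carrier holds")
    rng = np.random.default_rng(rng_seed)
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(spec.n_painful + spec.n_painless)],
            "group": ["painful"] * spec.n_painful + ["painless"] * spec.n_painless,
        }
    )
    painful_ids = participants.loc[participants.group == "painful", "participant_id"].to_numpy()
    painless_ids = participants.loc[participants.group == "painless", "participant_id"].to_numpy()
    n_painful_carriers = spec.n_carriers - spec.carriers_in_painless
    carriers = list(rng.choice(painful_ids, size=n_painful_carriers, replace=False))
    carriers += list(rng.choice(painless_ids, size=spec.carriers_in_painless, replace=False))

    # variant -> carriers: carrier 0 holds `multi_variant_count` variants,
    # one variant is shared by `shared_variant_carriers` carriers, the rest 1:1
    assignment: list[list[str]] = [[] for _ in range(spec.n_variants)]
    if carriers:
        vi = 0
        for _ in range(min(spec.multi_variant_count, spec.n_variants)):
            assignment[vi].append(carriers[0])
            vi += 1
        ci = 1
        if vi < spec.n_variants and len(carriers) > ci:
            take = min(spec.shared_variant_carriers, len(carriers) - ci)
            assignment[vi] = carriers[ci:ci + take]
            vi += 1
            ci += take
        while vi < spec.n_variants:
            assignment[vi].append(carriers[ci % len(carriers)] if ci < len(carriers) else carriers[-1])
            vi += 1
            ci += 1

    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for j in range(spec.n_variants):
        flagged = j < spec.n_literature_flagged
        maf_evs = float(10 ** rng.uniform(-5, -2.5))
        maf_exac = float(10 ** rng.uniform(-5, -2.5))
        if flagged and j == 0:
            maf_evs = maf_exac = 0.025  # literature override exercises the rule
        observed_evs = bool(rng.random() < 0.7) or (flagged and j == 0)
        # two unanimity-pathogenic variants mirror the functionally tested pair
        if j >= spec.n_variants - 2:
            preds = {p: "pathogenic" for p in PREDICTORS}
        else:
            preds = {
                p: rng.choice(["pathogenic", "benign", "unknown"], p=[0.4, 0.4, 0.2])
                for p in PREDICTORS
            }
        rows.append(
            {
                "variant_id": f"var{j + 1:02d}",
                "protein_change": "p.%s%d%s" % (
                    rng.choice(aa), int(rng.integers(50, 1950)), rng.choice(aa)
                ),
                "maf_evs": maf_evs if observed_evs else np.nan,
                "maf_exac": maf_exac,
                "literature_pain_flag": flagged,
                **{f"pred_{p}": preds[p] for p in PREDICTORS},
                "carrier_ids": ",".join(assignment[j]),
            }
        )
    return pd.DataFrame(rows), participants
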