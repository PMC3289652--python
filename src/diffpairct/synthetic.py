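"""Synthetic serum RT-qPCR cohort generator with planted ground truth.

The generator emulates the statistical structure a pairwise-ΔCt screen
assumes about serum qPCR data:

* per-miRNA baseline Ct levels (abundance differences between targets),
* a per-sample global Ct offset (serum input / extraction / RT-efficiency
  variability — the nuisance that diffpairs cancel and that single-miRNA
  thresholds are exposed to),
* additive disease effects on chosen miRNAs in cancer samples (a k-cycle
  Ct shift corresponds to a 2^k fold-change),
* Gaussian per-replicate measurement noise (heavier-tailed Student-t noise
  behind a flag),
* replicate RT/qPCR reactions, and
* right-censoring at the instrument cycle limit, with a configurable
  fraction of miRNAs whose baselines sit above the limit so they censor
  (the targets the global-undetected filter removes).

Ct(sample, miRNA, replicate) = baseline(miRNA) + shift(sample)
                               + effect(miRNA)·1[cancer] + noise,
values above the cycle limit censored at the limit.

Identical config + seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr_io import CtMatrix, write_ct_table


@dataclass
class SimulationConfig:
    """Parameters of one simulated two-phase cohort.

    All Ct quantities are in cycles.  ``effect_pairs`` lists
    (mirna_index, effect_size) shifts added to cancer samples; an effect
    miRNA paired against any stable miRNA yields a discriminative diffpair.
    """

    n_mirnas: int = 40
    n_cancer_train: int = 30
    n_control_train: int = 20
    n_cancer_test: int = 55
    n_control_test: int = 75
    baseline_ct_mean_range: tuple[float, float] = (22.0, 36.0)
    baseline_sd: float = 0.8
    sample_shift_sd: float = 1.5
    effect_pairs: list[tuple[int, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    n_replicates: int = 2
    cycle_limit: float = 40.0
    censor_fraction_null: float = 0.0
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_mirnas, self.n_cancer_train, self.n_control_train,
                  self.n_cancer_test, self.n_control_test, self.n_replicates)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.baseline_sd < 0 or self.sample_shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.censor_fraction_null <= 1:
            raise ValueError("censor_fraction_null must be in [0, 1]")
        for idx, _ in self.effect_pairs:
            if not 0 <= idx < self.n_mirnas:
                raise ValueError(f"effect index {idx} out of range")


@dataclass
class TruthManifest:
    """Record of what was planted, for ground-truth checks downstream."""

    seed: int
    effect_mirnas: dict[str, float]
    baselines: dict[str, float]
    censored_design: list[str]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[CtMatrix], pd.DataFrame, TruthManifest]:
    """Simulate replicate Ct matrices, cohort metadata and the truth manifest."""
    for split, n_ca, n_co in (("train", cfg.n_cancer_train, cfg.n_control_train),
                              ("test", cfg.n_cancer_test, cfg.n_control_test)):
        if n_ca == 0 or n_co == 0:
            raise ValueError(f"{split} split needs both cancers and controls")
    rng = np.random.default_rng(cfg.seed)

    mirna_ids = [f"miR-{i:03d}" for i in range(cfg.n_mirnas)]
    lo, hi = cfg.baseline_ct_mean_range
    # per-miRNA baseline abundance: mean uniform over the panel's dynamic
    # range, jittered by baseline_sd; fixed across samples and replicates
    baselines = (rng.uniform(lo, hi, size=cfg.n_mirnas)
                 + rng.normal(0.0, cfg.baseline_sd, size=cfg.n_mirnas))
    # a chosen fraction of null miRNAs is pushed above the cycle limit so
    # they never amplify — the columns the global-undetected filter removes
    effect_idx = {i for i, _ in cfg.effect_pairs}
    null_idx = np.array([i for i in range(cfg.n_mirnas) if i not in effect_idx])
    n_censor = int(round(cfg.censor_fraction_null * len(null_idx)))
    censor_design: list[str] = []
    if n_censor:
        chosen = rng.choice(null_idx, size=n_censor, replace=False)
        # far enough above the limit that sample shifts cannot rescue them
        baselines[chosen] = cfg.cycle_limit + 8.0
        censor_design = [mirna_ids[i] for i in sorted(chosen)]

    effects = np.zeros(cfg.n_mirnas)
    for idx, size in cfg.effect_pairs:
        effects[idx] += size

    groups, splits = [], []
    for split, n_ca, n_co in (("train", cfg.n_cancer_train, cfg.n_control_train),
                              ("test", cfg.n_cancer_test, cfg.n_control_test)):
        groups += ["cancer"] * n_ca + ["control"] * n_co
        splits += [split] * (n_ca + n_co)
    n_samples = len(groups)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    is_cancer = np.array([g == "cancer" for g in groups])

    shifts = rng.normal(0.0, cfg.sample_shift_sd, size=n_samples)
    signal = (baselines[None, :] + shifts[:, None]
              + np.outer(is_cancer, effects))

    matrices = []
    for _ in range(cfg.n_replicates):
        if cfg.heavy_tails:
            noise = cfg.noise_sd * rng.standard_t(5, size=signal.shape)
        else:
            noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape)
        ct = signal + noise
        censored = ct > cfg.cycle_limit
        ct = np.where(censored, cfg.cycle_limit, ct)
        # qPCR cannot report non-positive cycles; clip far-left tails
        ct = np.clip(ct, 1.0, None)
        matrices.append(CtMatrix(
            pd.DataFrame(ct, index=sample_ids, columns=mirna_ids),
            pd.DataFrame(censored, index=sample_ids, columns=mirna_ids),
            cfg.cycle_limit,
        ))

    meta = _demographics(rng, sample_ids, groups, splits)
    truth = TruthManifest(
        seed=cfg.seed,
        effect_mirnas={mirna_ids[i]: float(s) for i, s in cfg.effect_pairs},
        baselines={m: float(b) for m, b in zip(mirna_ids, baselines)},
        censored_design=censor_design,
        config=dataclasses.asdict(cfg),
    )
    return matrices, meta, truth


def _demographics(rng, sample_ids, groups, splits) -> pd.DataFrame:
    """Metadata with smoking rates per group/split matching the study cohorts."""
    smoking_rate = {("control", "train"): 0.45, ("cancer", "train"): 0.80,
                    ("control", "test"): 0.87, ("cancer", "test"): 1.00}
    rows = []
    for sid, g, sp in zip(sample_ids, groups, splits):
        cancer = g == "cancer"
        rows.append({
            "sample_id": sid, "group": g, "split": sp,
            "age": int(np.clip(rng.normal(67 if cancer else 62, 8), 20, 90)),
            "sex": "F" if rng.random() < 0.42 else "M",
            "smoker": bool(rng.random() < smoking_rate[(g, sp)]),
            "stage": rng.choice(["I", "II", "III", "IV"],
                                p=[0.5, 0.26, 0.2, 0.04]) if cancer else "",
            "histology": rng.choice(["adenocarcinoma", "squamous"],
                                    p=[0.6, 0.4]) if cancer else "",
        })
    return pd.DataFrame(rows)


def paper_shaped_cohort(
    seed: int = 0,
    effect_pairs: list[tuple[int, float]] | None = None,
    n_mirnas: int = 181,
) -> tuple[list[CtMatrix], pd.DataFrame, TruthManifest]:
    """Convenience preset with the reference cohort geometry.

    181 miRNAs; training split 30 cancers / 20 controls; test split 55
    cancers / 75 controls; two RT/qPCR replicates.  By default one miRNA
    carries a 3-cycle disease shift, so one family of diffpairs against
    stable partners is discoverable.
    """
    if effect_pairs is None:
        effect_pairs = [(0, 3.0)]
    cfg = SimulationConfig(
        n_mirnas=n_mirnas,
        n_cancer_train=30, n_control_train=20,
        n_cancer_test=55, n_control_test=75,
        effect_pairs=effect_pairs,
        n_replicates=2,
        seed=seed,
    )
    return simulate_cohort(cfg)


def write_cohort(out_dir: str | Path, matrices, meta, truth) -> dict[str, str]:
    """Write the simulated cohort in the CSV dialects the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for r, m in enumerate(matrices, start=1):
        p = out / f"ct_replicate_{r}.csv"
        write_ct_table(m, p)
        paths[f"ct_replicate_{r}"] = str(p)
    meta_path = out / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    paths["metadata"] = str(meta_path)
    truth_path = out / "truth_manifest.json"
    truth.to_json(truth_path)
    paths["truth_manifest"] = str(truth_path)
    return paths
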