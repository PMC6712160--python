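"""Seeded synthetic cohorts with planted sponge (ceRNA) structure.

The generator emulates the statistical shape of a tumour RNA-seq compilation:
three biotypes with mRNA >> lncRNA >> miRNA counts, RPKM-scale values with a
small structural-zero fraction, a handful of planted mRNA-lncRNA-miRNA
triplets whose members co-vary with sponge sign structure (mRNA and lncRNA
positively correlated, the miRNA anti-correlated with both), survival times
from an exponential proportional-hazards model tied to designated RNAs, and
tumour stages concentrated in III-IV with a small missing fraction.
Structural zeros model a detection limit: the lowest ``zero_rate`` fraction
of each transcript's values is reported as zero, mimicking dropout of
low-abundance measurements rather than missingness at random.

Sponge model
------------
Each planted triplet draws two correlated standard-normal latent factors
``u`` and ``w`` (``corr(u, w) = factor_corr``) per sample.  On the log2
scale the lncRNA loads ``+effect_loading`` on ``u``, the miRNA loads
``-effect_loading`` on ``w``, and the mRNA loads ``effect_loading/sqrt(2)``
on ``u + w``; independent Gaussian noise (``noise_sd``) is added to every
member.  The two-factor construction keeps all three pairwise associations
symmetric and sign-correct while leaving each member with partner-specific
signal, so that conditional (partial-correlation) feature selection can
recover every edge of the triangle, not just the strongest one.  Background
transcripts are independent noise around transcript-specific baselines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import STAGES, ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

# log2-RPKM baseline abundance distribution for all transcripts
_BASELINE_MEAN = 3.0
_BASELINE_SD = 1.5
# exponential baseline hazard: median survival 36 months at zero linear predictor
_BASELINE_MEDIAN_MONTHS = 36.0


class ConfigurationError(ValueError):
    """A SimConfig field violates its invariant; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 200 mRNA / 100 lncRNA / 30 miRNA over 200 samples (preserving the
    real compilation's biotype ordering), 12 planted triplets, strong sponge
    signal (``effect_loading=5``, ``noise_sd=0.2``), 1% structural zeros, six
    survival-linked and six stage-linked RNAs (the stage shift of 0.5 log2
    units per ordinal step is strongly detectable by ANOVA yet keeps the
    stage-driven co-expression among stage RNAs below the network's
    adjusted-R-squared filter, so stage is an annotation channel, not a
    network confound), and a stage distribution
    proportional to the real cohort's 20/323/60 stage II/III/IV samples with
    4 missing out of 407.
    """

    n_mrna: int = 200
    n_lncrna: int = 100
    n_mirna: int = 30
    n_samples: int = 200
    n_triplets: int = 12
    effect_loading: float = 5.0
    noise_sd: float = 0.2
    factor_corr: float = 0.5
    zero_rate: float = 0.01
    n_survival_rnas: int = 6
    hazard_coef: float = 1.0
    censor_rate: float = 0.3
    n_stage_rnas: int = 6
    stage_shift: float = 0.5
    stage_probs: tuple[float, float, float, float] = (20 / 407, 323 / 407, 60 / 407, 4 / 407)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_samples", "n_triplets",
                     "n_survival_rnas", "n_stage_rnas"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ConfigurationError(
                "n_triplets: exceeds min(n_mrna, n_lncrna, n_mirna)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd: must be > 0")
        if self.effect_loading < 0:
            raise ConfigurationError("effect_loading: must be >= 0")
        if not 0.0 <= self.zero_rate <= 1.0:
            raise ConfigurationError("zero_rate: must lie in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate: must lie in [0, 1]")
        if not -1.0 < self.factor_corr < 1.0:
            raise ConfigurationError("factor_corr: must lie in (-1, 1)")
        probs = np.asarray(self.stage_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any():
            raise ConfigurationError("stage_probs: four non-negative probabilities required")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ConfigurationError("stage_probs: must sum to 1")
        if self.n_survival_rnas > self.n_mrna:
            raise ConfigurationError("n_survival_rnas: exceeds n_mrna")
        n_background_mrna = self.n_mrna - max(self.n_triplets, self.n_survival_rnas)
        if self.n_stage_rnas > max(n_background_mrna, 0):
            raise ConfigurationError(
                "n_stage_rnas: not enough background mRNAs left after triplet/survival assignment")


@dataclass
class GroundTruth:
    """What was planted: edges and triplets (typed id tuples), plus the RNAs
    wired to the hazard and to tumour stage."""

    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    survival_rnas: set[str] = field(default_factory=set)
    stage_rnas: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": sorted(map(list, self.planted_edges)),
            "planted_triplets": sorted(map(list, self.planted_triplets)),
            "survival_rnas": sorted(self.survival_rnas),
            "stage_rnas": sorted(self.stage_rnas),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_edges={tuple(e) for e in payload["planted_edges"]},
            planted_triplets={tuple(t) for t in payload["planted_triplets"]},
            survival_rnas=set(payload["survival_rnas"]),
            stage_rnas=set(payload["stage_rnas"]),
        )


def _edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate one seeded cohort: expression (RPKM), clinical table, truth.

    Deterministic given ``config`` (including its seed): identical configs
    produce byte-identical serialized outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mrna_ids = [f"MRNA{i:05d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i:05d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i:05d}" for i in range(config.n_mirna)]
    ids = mrna_ids + lnc_ids + mir_ids
    biotypes = pd.Series(
        ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna + ["miRNA"] * config.n_mirna,
        index=ids,
    )
    n_tr, n_s = len(ids), config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n_s)]

    # background: independent noise around per-transcript baselines (log2 scale)
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_tr)
    log2 = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_tr, n_s))
    row = {tid: i for i, tid in enumerate(ids)}

    truth = GroundTruth()
    lam, eta = config.effect_loading, config.factor_corr
    for t in range(config.n_triplets):
        m, l, r = mrna_ids[t], lnc_ids[t], mir_ids[t]
        u = rng.standard_normal(n_s)
        w = eta * u + np.sqrt(1.0 - eta**2) * rng.standard_normal(n_s)
        log2[row[m]] += lam / np.sqrt(2.0) * (u + w)
        log2[row[l]] += lam * u
        log2[row[r]] += -lam * w
        truth.planted_triplets.add((m, l, r))
        truth.planted_edges.update({_edge(m, l), _edge(m, r), _edge(l, r)})

    # survival RNAs: mRNA members of the first triplets, padded from background
    surv: list[str] = [mrna_ids[t] for t in range(min(config.n_survival_rnas, config.n_triplets))]
    pad = config.n_survival_rnas - len(surv)
    if pad > 0:
        surv.extend(mrna_ids[config.n_triplets:config.n_triplets + pad])
    truth.survival_rnas = set(surv)

    # stage RNAs: background mRNAs disjoint from triplets and survival padding
    first_free = max(config.n_triplets, config.n_survival_rnas)
    stage_rnas = mrna_ids[first_free:first_free + config.n_stage_rnas]
    truth.stage_rnas = set(stage_rnas)

    # stage: latent II/III/IV stage for every sample, then a missing-label mask
    probs = np.asarray(config.stage_probs, dtype=float)
    p_missing = probs[3]
    cond = probs[:3] / probs[:3].sum() if probs[:3].sum() > 0 else np.array([0.0, 1.0, 0.0])
    latent_idx = rng.choice(3, size=n_s, p=cond)
    missing_mask = rng.random(n_s) < p_missing
    stage_labels = np.array([STAGES[i] for i in latent_idx], dtype=object)
    stage_labels[missing_mask] = np.nan

    for tid in stage_rnas:
        log2[row[tid]] += config.stage_shift * latent_idx

    # survival: exponential PH on the (centred) mean expression of survival RNAs
    if surv:
        lp = config.hazard_coef * log2[[row[tid] for tid in surv]].mean(axis=0)
        lp = lp - lp.mean()
    else:
        lp = np.zeros(n_s)
    base_rate = np.log(2.0) / _BASELINE_MEDIAN_MONTHS
    t_true = rng.exponential(1.0, size=n_s) / (base_rate * np.exp(lp))
    censored = rng.random(n_s) < config.censor_rate
    os_months = np.where(censored, rng.uniform(0.0, 1.0, size=n_s) * t_true, t_true)
    event = (~censored).astype(int)

    # back to RPKM scale; structural zeros emulate a detection limit: the
    # lowest zero_rate fraction of each transcript's values drops to zero
    rpkm = np.exp2(log2)
    n_zero = int(round(config.zero_rate * n_s))
    if n_zero > 0:
        order = np.argsort(rpkm, axis=1, kind="stable")
        rows_ix = np.repeat(np.arange(n_tr), n_zero)
        cols_ix = order[:, :n_zero].ravel()
        rpkm[rows_ix, cols_ix] = 0.0

    expr = ExpressionMatrix(
        pd.DataFrame(rpkm, index=ids, columns=sample_ids), biotypes)
    clinical = ClinicalTable(pd.DataFrame(
        {"os_months": os_months, "event": event, "stage": stage_labels},
        index=pd.Index(sample_ids, name="sample_id")))
    return expr, clinical, truth


def stage_distribution_check(clinical: ClinicalTable) -> dict[str, int]:
    """Count samples per stage label (including ``missing``); counts sum to n."""
    if clinical.df.empty:
        raise ValueError("clinical table is empty")
    stages = clinical.df["stage"]
    counts = {label: int((stages == label).sum()) for label in STAGES}
    counts["missing"] = int(stages.isna().sum())
    assert sum(counts.values()) == len(clinical.df)
    return counts


def write_cohort(outdir: str | Path, expr: ExpressionMatrix, clinical: ClinicalTable,
                 truth: GroundTruth) -> dict[str, Path]:
    """Serialize a cohort into a directory of TSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "clinical": outdir / "clinical.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    expr.to_tsv(paths["expression"], paths["annotation"])
    clinical.to_tsv(paths["clinical"])
    truth.to_json(paths["ground_truth"])
    logger.info("cohort written to %s (%d transcripts, %d samples)",
                outdir, expr.n_transcripts, expr.n_samples)
    return paths


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{sorted(unknown)[0]}: unknown field")
    if "stage_probs" in raw:
        raw["stage_probs"] = tuple(raw["stage_probs"])
    return SimConfig(**raw)
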