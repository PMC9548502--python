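"""Synthetic TCR repertoire cohorts with a plantable benign/malignant effect.

The generator emulates the statistical structure that the downstream
analysis assumes, so every stage can be exercised without access to real
sequencing data:

* heavy-tailed clone-size spectra (roughened Zipf tail plus an expanded
  "head" of clonally expanded cells),
* lower repertoire diversity and an excess of hyperexpanded clones in
  malignant subjects,
* public clones shared across subjects through a common sequence pool,
* a plantable CDR3β amino-acid motif spiked into malignant repertoires,
* correlated clinical covariates (GGN status, nodule size, age, sex,
  tumour stage).

The class effect on diversity is planted *directly on the Shannon entropy*:
each subject draws a target entropy around the entropy of the class
reference spectrum — a Zipf distribution over ``clones_per_subject`` ranks
with the class hyperexpansion boost moved into the top clones — and the
realised spectrum is tempered (a solved exponent on the tail log-weights)
until it matches the target.  All remaining shape degrees of freedom
(realised clone count, expanded-clone mass and its allocation, tail tilt
and roughness, sequencing depth) vary independently of the class label, so
they act as biological nuisance rather than as additional label leaks.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import ClonotypeRecord, Repertoire, SubjectMetadata

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_N_TOP_BOOSTED = 5  # clones receiving the hyperexpansion boost in the reference


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of a synthetic benign/malignant nodule cohort.

    Class-level knobs (exponents, boost, GGN rates, motif spike rate) carry
    the planted effects; the remaining parameters control class-independent
    between-subject variability.
    """

    n_benign: int = 50
    n_malignant: int = 50
    clones_per_subject: int = 1000
    reads_per_subject: int = 20000
    powerlaw_exponent_benign: float = 1.05
    powerlaw_exponent_malignant: float = 1.25
    hyperexpanded_boost_malignant: float = 0.04
    # between-subject nuisance variability (class independent)
    shannon_sd: float = 0.35          # sd of the per-subject target entropy, nats
    richness_sd: float = 0.55         # lognormal sd of the realised clone count
    depth_sd: float = 0.55            # lognormal sd of sequencing depth
    base_expansion: float = 0.05      # expanded-clone mass present in both classes
    expansion_jitter_sd: float = 0.8  # lognormal sd of the expanded mass
    n_expanded_clones: int = 40       # median size of the expanded head
    tail_tilt_range: tuple[float, float] = (0.6, 1.4)
    tail_roughness_range: tuple[float, float] = (0.8, 2.0)
    # sequence-level structure
    public_clone_pool_size: int = 2000
    public_clone_rate: float = 0.10
    planted_motif: str = "SSGGSSYEQYF"
    motif_spike_rate_malignant: float = 0.10
    motif_spike_rate_benign: float = 0.0
    cdr3_length_range: tuple[int, int] = (8, 20)
    # clinical covariates
    ggn_rate_benign: float = 0.02
    ggn_rate_malignant: float = 0.92
    nodule_size_params: dict = field(
        default_factory=lambda: {
            "benign": {"median_mm": 12.0, "sigma": 0.4},
            "malignant": {"median_mm": 16.0, "sigma": 0.4},
        }
    )
    age_params: dict = field(
        default_factory=lambda: {
            "benign": {"mean": 54.0, "sd": 10.0},
            "malignant": {"mean": 59.0, "sd": 10.0},
        }
    )
    stage_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.n_benign + self.n_malignant == 0:
            raise ConfigError("cohort must contain at least one subject")
        if self.clones_per_subject < 1 or self.reads_per_subject < 1:
            raise ConfigError("clones_per_subject and reads_per_subject must be >= 1")
        for name in ("powerlaw_exponent_benign", "powerlaw_exponent_malignant"):
            if not getattr(self, name) > 1:
                raise ConfigError(f"{name} must be > 1")
        if self.hyperexpanded_boost_malignant < 0:
            raise ConfigError("hyperexpanded_boost_malignant must be >= 0")
        for name in (
            "public_clone_rate",
            "motif_spike_rate_malignant",
            "motif_spike_rate_benign",
            "ggn_rate_benign",
            "ggn_rate_malignant",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.public_clone_pool_size < 0:
            raise ConfigError("public_clone_pool_size must be >= 0")
        if self.public_clone_rate > 0 and self.public_clone_pool_size == 0:
            raise ConfigError(
                "public_clone_rate > 0 requires a non-empty public clone pool"
            )
        if self.base_expansion + self.hyperexpanded_boost_malignant >= 1:
            raise ConfigError("total expansion mass must be < 1")
        lo, hi = self.cdr3_length_range
        if not (3 <= lo <= hi):
            raise ConfigError("cdr3_length_range must satisfy 3 <= lo <= hi")
        if abs(sum(self.stage_probs) - 1) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")
        if set(self.planted_motif) - set("ACDEFGHIKLMNPQRSTVWY"):
            raise ConfigError("planted_motif must use the 20 canonical amino acids")


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _zipf(alpha: float, size: int) -> np.ndarray:
    w = np.arange(1, size + 1, dtype=float) ** -alpha
    return w / w.sum()


def reference_entropy(config: CohortSimConfig, label: str) -> float:
    """Entropy of the idealised class spectrum the generator targets.

    The reference is a Zipf spectrum over ``clones_per_subject`` ranks with
    the class expansion mass (``base_expansion`` plus, for malignant, the
    hyperexpansion boost) moved into the top clones.  It is strictly
    decreasing in the boost, so raising the boost lowers expected Shannon.
    """
    alpha = (
        config.powerlaw_exponent_malignant
        if label == "malignant"
        else config.powerlaw_exponent_benign
    )
    boost = config.base_expansion + (
        config.hyperexpanded_boost_malignant if label == "malignant" else 0.0
    )
    w = _zipf(alpha, config.clones_per_subject)
    q = (1 - boost) * w
    top = min(_N_TOP_BOOSTED, len(w))
    q[:top] += boost * (w[:top] / w[:top].sum())
    return _entropy(q)


def _temper(log_w: np.ndarray, beta: float) -> np.ndarray:
    z = beta * log_w
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def _solve_temperature(
    log_w: np.ndarray, target: float, lo: float = 0.2, hi: float = 5.0, iters: int = 40
) -> float:
    """Exponent beta such that entropy(softmax(beta * log_w)) == target.

    Entropy is strictly decreasing in beta; the target is clipped into the
    attainable range before bisection.
    """
    h_lo, h_hi = _entropy(_temper(log_w, lo)), _entropy(_temper(log_w, hi))
    target = min(max(target, h_hi + 1e-3), h_lo - 1e-3)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if _entropy(_temper(log_w, mid)) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _random_sequences(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[str]:
    if n == 0:
        return []
    lengths = rng.integers(lo, hi + 1, size=n)
    letters = _AA[rng.integers(0, len(_AA), size=int(lengths.sum()))]
    out, pos = [], 0
    for length in lengths:
        out.append("".join(letters[pos : pos + length]))
        pos += length
    return out


def _motif_sequences(
    rng: np.random.Generator, n: int, motif: str, lo: int, hi: int
) -> list[str]:
    """Random CDR3 sequences each containing *motif* as a substring."""
    lo = max(lo, len(motif))
    hi = max(hi, len(motif))
    base = _random_sequences(rng, n, lo, hi)
    out = []
    for s in base:
        pos = int(rng.integers(0, len(s) - len(motif) + 1))
        out.append(s[:pos] + motif + s[pos + len(motif) :])
    return out


def make_public_pool(config: CohortSimConfig, seed_seq: np.random.SeedSequence) -> list[str]:
    """Cohort-wide pool of public CDR3β sequences (motif-free)."""
    rng = np.random.default_rng(seed_seq)
    lo, hi = config.cdr3_length_range
    return _random_sequences(rng, config.public_clone_pool_size, lo, hi)


def _clone_probabilities(
    config: CohortSimConfig, label: str, rng: np.random.Generator
) -> np.ndarray:
    """Sample one subject's clone-probability spectrum (head + tail)."""
    boost = config.hyperexpanded_boost_malignant if label == "malignant" else 0.0
    target_h = reference_entropy(config, label) + rng.normal(0.0, config.shannon_sd)

    k = max(10, int(rng.lognormal(np.log(config.clones_per_subject), config.richness_sd)))
    m = min(
        (config.base_expansion + boost) * rng.lognormal(0.0, config.expansion_jitter_sd),
        0.7,
    )
    n_exp = max(3, int(rng.lognormal(np.log(config.n_expanded_clones), 1.0)))
    conc = rng.uniform(0.2, 2.0)
    alloc = rng.dirichlet(np.full(n_exp, conc)) + 1e-12
    alloc /= alloc.sum()

    tilt = rng.uniform(*config.tail_tilt_range)
    rough = rng.uniform(*config.tail_roughness_range)
    log_tail = -tilt * np.log(np.arange(1, k + 1, dtype=float))
    log_tail += rough * rng.standard_normal(k)

    # split the target entropy between the fixed head and the tempered tail:
    # H = (1-m) H_tail + m H_alloc - m ln m - (1-m) ln(1-m)
    h_alloc = _entropy(alloc)
    h_tail = (target_h - m * h_alloc + m * np.log(m) + (1 - m) * np.log(1 - m)) / (1 - m)
    beta = _solve_temperature(log_tail, h_tail)
    tail = _temper(log_tail, beta)
    return np.concatenate([m * alloc, (1 - m) * tail])


def simulate_repertoire(
    config: CohortSimConfig,
    label: str,
    rng: np.random.Generator,
    subject_id: str = "S1",
    public_pool: Sequence[str] | None = None,
) -> Repertoire:
    """Draw one subject's repertoire for the given class label.

    ``public_pool`` defaults to a pool derived from ``config.seed`` so that
    stand-alone calls still produce shared sequences; :func:`simulate_cohort`
    passes one pool to every subject.
    """
    config.validate()
    if label not in ("benign", "malignant"):
        raise ConfigError(f"unknown class label {label!r}")
    if public_pool is None:
        public_pool = make_public_pool(
            config, np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
        )

    p = _clone_probabilities(config, label, rng)
    reads = max(
        2000, int(rng.lognormal(np.log(config.reads_per_subject), config.depth_sd))
    )
    counts = rng.multinomial(reads, p)

    spike_rate = (
        config.motif_spike_rate_malignant
        if label == "malignant"
        else config.motif_spike_rate_benign
    )
    n = len(p)
    u_spike = rng.random(n)
    u_public = rng.random(n)
    pool_idx = (
        rng.integers(0, len(public_pool), size=n) if public_pool else np.zeros(n, int)
    )
    lo, hi = config.cdr3_length_range
    is_spike = u_spike < spike_rate
    is_public = (~is_spike) & (u_public < config.public_clone_rate) & (len(public_pool) > 0)
    motif_seqs = iter(
        _motif_sequences(rng, int(is_spike.sum()), config.planted_motif, lo, hi)
    )
    private_seqs = iter(
        _random_sequences(rng, int(n - is_spike.sum() - is_public.sum()), lo, hi)
    )

    records = []
    for i in range(n):
        if counts[i] == 0:
            # sequence streams must still advance deterministically
            if is_spike[i]:
                next(motif_seqs)
            elif not is_public[i]:
                next(private_seqs)
            continue
        if is_spike[i]:
            seq = next(motif_seqs)
        elif is_public[i]:
            seq = public_pool[pool_idx[i]]
        else:
            seq = next(private_seqs)
        records.append(ClonotypeRecord(cdr3_aa=seq, count=int(counts[i])))
    return Repertoire.from_records(subject_id, records)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[Repertoire], list[SubjectMetadata]]:
    """Simulate a full cohort (repertoires plus clinical metadata).

    One global seed fans out to per-subject substreams via spawned
    ``SeedSequence`` children keyed by subject index, so the cohort is
    reproducible independent of evaluation order.
    """
    config.validate()
    root = np.random.SeedSequence(entropy=config.seed)
    pool_seed, meta_seed, *subject_seeds = root.spawn(
        2 + config.n_benign + config.n_malignant
    )
    public_pool = make_public_pool(config, pool_seed)
    meta_rng = np.random.default_rng(meta_seed)

    labels = ["benign"] * config.n_benign + ["malignant"] * config.n_malignant
    repertoires: list[Repertoire] = []
    metadata: list[SubjectMetadata] = []
    n_digits = max(3, len(str(len(labels))))
    for i, (label, sseed) in enumerate(zip(labels, subject_seeds)):
        sid = ("B" if label == "benign" else "M") + str(i + 1).zfill(n_digits)
        rng = np.random.default_rng(sseed)
        repertoires.append(
            simulate_repertoire(config, label, rng, subject_id=sid, public_pool=public_pool)
        )
        ggn_rate = (
            config.ggn_rate_malignant if label == "malignant" else config.ggn_rate_benign
        )
        size_par = config.nodule_size_params[label]
        age_par = config.age_params[label]
        stage = None
        if label == "malignant":
            stage = ("I", "II", "III")[
                int(meta_rng.choice(3, p=np.asarray(config.stage_probs)))
            ]
        metadata.append(
            SubjectMetadata(
                subject_id=sid,
                label=label,
                stage=stage,
                ggn=bool(meta_rng.random() < ggn_rate),
                nodule_size_mm=float(
                    meta_rng.lognormal(np.log(size_par["median_mm"]), size_par["sigma"])
                ),
                age_years=float(
                    np.clip(meta_rng.normal(age_par["mean"], age_par["sd"]), 18, 95)
                ),
                sex="F" if meta_rng.random() < 0.5 else "M",
            )
        )
    return repertoires, metadata


def config_without_tcr_signal(config: CohortSimConfig) -> CohortSimConfig:
    """Variant where the repertoire carries no class signal (clinical only)."""
    return replace(
        config,
        powerlaw_exponent_malignant=config.powerlaw_exponent_benign,
        hyperexpanded_boost_malignant=0.0,
        motif_spike_rate_malignant=config.motif_spike_rate_benign,
    )


def config_without_clinical_signal(config: CohortSimConfig) -> CohortSimConfig:
    """Variant where the clinical covariates carry no class signal."""
    return replace(
        config,
        ggn_rate_malignant=config.ggn_rate_benign,
        nodule_size_params={
            "benign": dict(config.nodule_size_params["benign"]),
            "malignant": dict(config.nodule_size_params["benign"]),
        },
        age_params={
            "benign": dict(config.age_params["benign"]),
            "malignant": dict(config.age_params["benign"]),
        },
    )
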