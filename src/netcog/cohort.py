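"""Synthetic resting-state cohort generator.

Generates a seeded cohort with the statistical structure the downstream
stages assume: per-subject effective-connectivity (EC) matrices per network
with planted group-mean, group-difference and covariate effects plus
between-subject variability; stationary multichannel timeseries driven by
the subject's EC (exact OU discretization); noisy "posterior" EC estimates
standing in for a first-level model inversion; and cognitive scores in seven
domains plus a standardized composite, optionally carrying a planted
low-rank linear link to a chosen subset of EC parameters at a specified
canonical correlation.

Default cohort conditions mirror a two-group resting-state study: 74
controls (HC) and 66 patients (SZ), 145 timepoints at a 2 s sampling
interval, and demographic covariates (age, gender, antipsychotic medication
dose in chlorpromazine equivalents, zero for controls).

Randomness is organised as one global seed that fans out to per-subject
substreams, so changing the cohort size never reshuffles earlier subjects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import NetworkLayout, make_layout
from .linsys import effective_matrix, is_stable, simulate_ou

__all__ = [
    "DOMAINS",
    "SimulationConfig",
    "SubjectRecord",
    "ECPosterior",
    "CognitiveScores",
    "Cohort",
    "ec_feature_names",
    "simulate_true_ec",
    "simulate_timeseries",
    "make_ec_posteriors",
    "simulate_cognition",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The seven cognitive domains of the consensus battery, in canonical order.
DOMAINS = (
    "speed_of_processing",
    "attention_vigilance",
    "working_memory",
    "verbal_learning",
    "visual_learning",
    "reasoning_problem_solving",
    "social_cognition",
)

_STABILITY_RETRIES = 100
_SHRINK_STEPS = 60


@dataclass
class SimulationConfig:
    """Conditions for the synthetic cohort.

    Parameters
    ----------
    n_hc, n_sz
        Subject counts per group.
    n_timepoints, dt
        Timeseries length and sampling interval in seconds.
    mean_extrinsic_scale
        Scale of group-mean extrinsic (off-diagonal) EC in Hz; the per-entry
        SD is ``mean_extrinsic_scale / sqrt(n)`` for an n-node network so
        the spectral radius of the coupling stays below the −0.5 Hz
        self-inhibition regardless of network size.
    self_log_sd
        SD of group-mean self-connection log-scalings around 0.
    ec_noise_sd
        Between-subject EC SD: in Hz on extrinsic entries, in log-scaling
        units on the diagonal.
    estimation_noise_sd
        SD of the perturbation applied to true EC to emulate first-level
        estimation; also sets the reported posterior variance.
    diff_fraction, diff_effect
        Fraction of extrinsic connections per network carrying a group
        difference, and the SZ−HC effect size in Hz (sign-balanced across
        the selected connections).
    covariate_effects
        Map of covariate name (age, gender, medication) to an EC effect in
        Hz per SD of the (standardized) covariate, applied to a seeded
        random ``diff_fraction`` subset of extrinsic connections.
    group_deficit
        Mean shift (in SD units) added to every cognitive domain for SZ
        subjects; −1 reflects the typical reported impairment.
    planted_rho, planted_x_idx, planted_y_idx
        Target first canonical correlation between the chosen EC parameters
        (indices into the cohort-level EC feature vector) and the chosen
        cognitive domains (indices 0..6).
    q_scale
        Process-noise covariance is ``q_scale * I``.
    seed
        Global seed; all subject-level streams derive from it.
    """

    n_hc: int = 74
    n_sz: int = 66
    n_timepoints: int = 145
    dt: float = 2.0
    mean_extrinsic_scale: float = 0.3
    self_log_sd: float = 0.1
    ec_noise_sd: float = 0.05
    estimation_noise_sd: float = 0.01
    diff_fraction: float = 0.2
    diff_effect: float = 0.2
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "gender": 0.0, "medication": 0.0})
    group_deficit: float = -1.0
    planted_rho: float = 0.0
    planted_x_idx: tuple[int, ...] = ()
    planted_y_idx: tuple[int, ...] = ()
    q_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not (0.0 <= self.planted_rho < 1.0):
            raise ValueError("planted_rho must be in [0, 1)")
        if not (0.0 <= self.diff_fraction <= 1.0):
            raise ValueError("diff_fraction must be in [0, 1]")
        for name in ("ec_noise_sd", "estimation_noise_sd", "self_log_sd",
                     "mean_extrinsic_scale", "q_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_rho > 0 and (not self.planted_x_idx
                                     or not self.planted_y_idx):
            raise ValueError(
                "planted_rho > 0 requires planted_x_idx and planted_y_idx")
        if any(not 0 <= j < len(DOMAINS) for j in self.planted_y_idx):
            raise ValueError("planted_y_idx must index the 7 domains")


@dataclass
class SubjectRecord:
    """One subject's covariates and ground-truth EC.

    ``true_ec`` maps network name to a square matrix whose off-diagonal
    entries are rates in Hz (entry ``[t, s]`` is the influence of source
    ``s`` on target ``t``) and whose diagonal holds log-scaling
    self-connection parameters.
    """

    subject_id: str
    group: str  # "HC" or "SZ"
    age: float
    gender: str  # "F" or "M"
    medication: float  # CPZ-equivalent mg/day, 0 for HC
    true_ec: dict[str, np.ndarray]


@dataclass
class ECPosterior:
    """Per-subject EC posterior summaries (mean and variance per entry)."""

    subject_id: str
    means: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]

    def vector(self, layout: NetworkLayout) -> np.ndarray:
        """Vectorize all networks' posterior means in canonical order.

        Order is network order in the layout, then row-major within each
        network matrix — i.e. grouped by target (receiving) node.
        """
        return np.concatenate([self.means[name].ravel(order="C")
                               for name in layout.network_names])

    def variance_vector(self, layout: NetworkLayout) -> np.ndarray:
        return np.concatenate([self.variances[name].ravel(order="C")
                               for name in layout.network_names])


@dataclass
class CognitiveScores:
    subject_id: str
    domain_scores: dict[str, float]
    composite: float


@dataclass
class Cohort:
    """A complete simulated cohort plus its generating ground truth."""

    layout: NetworkLayout
    config: SimulationConfig
    records: list[SubjectRecord]
    posteriors: list[ECPosterior]
    cognition: list[CognitiveScores]
    truth: dict

    def covariate_table(self) -> pd.DataFrame:
        rows = [{"subject_id": r.subject_id, "group": r.group, "age": r.age,
                 "gender": r.gender, "medication": r.medication}
                for r in self.records]
        return pd.DataFrame(rows)

    def cognition_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cognition:
            row = {"subject_id": c.subject_id}
            row.update(c.domain_scores)
            row["composite"] = c.composite
            rows.append(row)
        return pd.DataFrame(rows)

    def ec_matrix(self) -> np.ndarray:
        """Subjects × EC-features matrix of posterior means."""
        return np.vstack([p.vector(self.layout) for p in self.posteriors])


def ec_feature_names(layout: NetworkLayout) -> list[str]:
    """Names of the vectorized EC features, ``network:source->target``.

    Self-connections are named ``network:label(self)``.  The order matches
    :meth:`ECPosterior.vector`.
    """
    names = []
    for net, labels in layout.networks:
        for t, tgt in enumerate(labels):
            for s, src in enumerate(labels):
                if s == t:
                    names.append(f"{net}:{tgt}(self)")
                else:
                    names.append(f"{net}:{src}->{tgt}")
    return names


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 13, index]))


def _cohort_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 7, stream]))


def _sample_mask(rng: np.random.Generator, n: int, fraction: float
                 ) -> np.ndarray:
    """Signed mask over the n(n-1) extrinsic entries of an n-node network.

    Returns an (n, n) int array with 0 off the mask and ±1 on it; signs are
    balanced (half +1, half −1, odd count favouring +1).
    """
    off = [(t, s) for t in range(n) for s in range(n) if t != s]
    k = int(round(fraction * len(off)))
    mask = np.zeros((n, n), dtype=int)
    if k == 0:
        return mask
    chosen = rng.choice(len(off), size=k, replace=False)
    signs = np.ones(k, dtype=int)
    signs[1::2] = -1
    for idx, sign in zip(chosen, signs):
        t, s = off[idx]
        mask[t, s] = sign
    return mask


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def simulate_true_ec(
    layout: NetworkLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SubjectRecord], dict]:
    """Generate per-subject ground-truth EC with planted group structure.

    Each subject's EC per network is
    group mean + (±1 group code)·(diff_effect/2) on a sign-balanced random
    subset of extrinsic connections + covariate terms + Gaussian
    between-subject noise; diagonals are generated in log-scaling space.
    Stability of the effective matrix is enforced by resampling the
    subject's noise (up to 100 retries) and then uniform shrinkage of the
    extrinsic entries.

    Returns ``(records, truth)`` where ``truth`` holds the signed
    difference masks and covariate masks per network.
    """
    del rng  # randomness is governed entirely by config.seed substreams
    cohort_rng = _cohort_rng(config.seed, 0)
    sizes = layout.sizes

    # group-level means and planted masks, one draw per network
    means, diff_masks, cov_masks = {}, {}, {}
    cov_names = ("age", "gender", "medication")
    for net in layout.network_names:
        n = sizes[net]
        extr_sd = config.mean_extrinsic_scale / np.sqrt(n)
        mean = cohort_rng.normal(0.0, extr_sd, size=(n, n))
        np.fill_diagonal(mean, cohort_rng.normal(0.0, config.self_log_sd,
                                                 size=n))
        means[net] = mean
        diff_masks[net] = _sample_mask(cohort_rng, n, config.diff_fraction)
        cov_masks[net] = {c: _sample_mask(cohort_rng, n, config.diff_fraction)
                          for c in cov_names
                          if config.covariate_effects.get(c, 0.0) != 0.0}

    # covariates (drawn per subject from substreams)
    n_total = config.n_hc + config.n_sz
    groups = ["HC"] * config.n_hc + ["SZ"] * config.n_sz
    ages, genders, meds = [], [], []
    for i in range(n_total):
        srng = _subject_rng(config.seed, i)
        age = float(np.clip(srng.normal(37.0, 12.0), 18.0, 65.0))
        p_female = 23 / 74 if groups[i] == "HC" else 13 / 66
        gender = "F" if srng.random() < p_female else "M"
        med = float(srng.lognormal(5.63, 0.75)) if groups[i] == "SZ" else 0.0
        ages.append(age)
        genders.append(gender)
        meds.append(med)

    cov_std = {
        "age": _standardize(np.array(ages)),
        "gender": _standardize(np.array([1.0 if g == "M" else 0.0
                                         for g in genders])),
        "medication": _standardize(np.array(meds)),
    }

    records: list[SubjectRecord] = []
    for i in range(n_total):
        # EC noise uses a stream distinct from the covariate stream so that
        # each is reproducible independently of the other's draw count
        srng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                             17, i]))
        gcode = 1.0 if groups[i] == "SZ" else -1.0
        true_ec: dict[str, np.ndarray] = {}
        for net in layout.network_names:
            n = sizes[net]
            base = means[net].copy()
            base += gcode * (config.diff_effect / 2.0) * diff_masks[net]
            for cname, cmask in cov_masks[net].items():
                base += (config.covariate_effects[cname]
                         * cov_std[cname][i] * cmask)
            # diagonal of base currently holds mean log-scalings; masks are
            # extrinsic-only so the diagonal is untouched above
            ec = None
            for attempt in range(_STABILITY_RETRIES):
                noise = srng.normal(0.0, config.ec_noise_sd, size=(n, n))
                cand = base + noise
                if is_stable(effective_matrix(cand)):
                    ec = cand
                    break
            if ec is None:
                # uniform shrinkage of extrinsic entries toward zero
                cand = base + srng.normal(0.0, config.ec_noise_sd,
                                          size=(n, n))
                for _ in range(_SHRINK_STEPS):
                    off = cand - np.diag(np.diag(cand))
                    cand = 0.9 * off + np.diag(np.diag(cand))
                    if is_stable(effective_matrix(cand)):
                        ec = cand
                        break
                if ec is None:
                    raise RuntimeError(
                        f"could not stabilize network {net!r} for subject "
                        f"{i} after {_STABILITY_RETRIES} resamples and "
                        f"{_SHRINK_STEPS} shrinkage steps")
            true_ec[net] = ec
        sid = f"{groups[i]}{i + 1:03d}"
        records.append(SubjectRecord(
            subject_id=sid, group=groups[i], age=ages[i],
            gender=genders[i], medication=meds[i], true_ec=true_ec))

    truth = {
        "diff_masks": {net: diff_masks[net].tolist()
                       for net in layout.network_names},
        "diff_effect": config.diff_effect,
        "covariate_masks": {net: {c: m.tolist()
                                  for c, m in cov_masks[net].items()}
                            for net in layout.network_names},
    }
    return records, truth


def simulate_timeseries(
    record: SubjectRecord,
    network: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one subject's stationary timeseries for one network.

    Exactly discretized OU process driven by the subject's effective
    matrix, process noise ``q_scale * I``.  Returns an
    ``(n_timepoints, n_subnetworks)`` array.
    """
    if network not in record.true_ec:
        raise KeyError(f"subject has no network {network!r}")
    A = effective_matrix(record.true_ec[network])
    if not is_stable(A):
        raise ValueError(f"effective matrix for {network!r} is unstable")
    Q = config.q_scale * np.eye(A.shape[0])
    return simulate_ou(A, Q, config.dt, config.n_timepoints, rng)


def make_ec_posteriors(
    records: list[SubjectRecord],
    layout: NetworkLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ECPosterior]:
    """Emulate first-level inversion: true EC plus Gaussian estimation noise.

    Posterior mean = true EC + N(0, estimation_noise_sd²); posterior
    variance = estimation_noise_sd² with a 1e-8 floor so downstream
    precision weighting is always defined.
    """
    del rng
    var = max(config.estimation_noise_sd ** 2, 1e-8)
    posteriors = []
    for i, rec in enumerate(records):
        srng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                             23, i]))
        means, variances = {}, {}
        for net in layout.network_names:
            true = rec.true_ec[net]
            noise = srng.normal(0.0, config.estimation_noise_sd,
                                size=true.shape)
            means[net] = true + noise
            variances[net] = np.full(true.shape, var)
        posteriors.append(ECPosterior(subject_id=rec.subject_id,
                                      means=means, variances=variances))
    return posteriors


def simulate_cognition(
    records: list[SubjectRecord],
    layout: NetworkLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[CognitiveScores]:
    """Generate domain scores with an optional planted EC-cognition link.

    A shared latent variate ``z`` (a unit-norm combination of the z-scored
    planted EC parameters, taken from the subjects' true EC) is injected
    into each planted domain with loading ``c`` chosen so the population
    first canonical correlation between the planted EC set and the planted
    domain set equals ``planted_rho``:

        c = rho / sqrt(k - (k - 1) rho²),   k = number of planted domains.

    Every domain additionally receives a group-level mean deficit
    (``group_deficit`` SD, default −1) for SZ subjects.  The composite is
    the cohort-standardized sum of the seven domains.
    """
    del rng
    n = len(records)
    scores = np.empty((n, len(DOMAINS)))
    for j in range(len(DOMAINS)):
        srngs = [np.random.default_rng(
            np.random.SeedSequence([config.seed, 29, i, j])) for i in range(n)]
        scores[:, j] = [r.standard_normal() for r in srngs]

    if config.planted_rho > 0:
        k = len(config.planted_y_idx)
        rho = config.planted_rho
        c = rho / np.sqrt(k - (k - 1) * rho ** 2)
        if not c < 1.0:
            raise ValueError("planted_rho incompatible with unit-variance "
                             "noise floor for the planted domains")
        X = np.vstack([
            np.concatenate([r.true_ec[net].ravel(order="C")
                            for net in layout.network_names])
            for r in records])
        xp = X[:, list(config.planted_x_idx)]
        sd = xp.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("planted EC parameters have zero variance")
        xp = (xp - xp.mean(axis=0)) / sd
        # equal unit-norm weights: every planted parameter participates
        # in the latent variate with the same loading
        w = np.full(xp.shape[1], 1.0 / np.sqrt(xp.shape[1]))
        z = _standardize(xp @ w)
        for j in config.planted_y_idx:
            scores[:, j] = c * z + np.sqrt(1 - c ** 2) * scores[:, j]

    deficit = np.array([config.group_deficit if r.group == "SZ" else 0.0
                        for r in records])
    scores += deficit[:, None]

    composite = _standardize(scores.sum(axis=1))
    out = []
    for i, rec in enumerate(records):
        out.append(CognitiveScores(
            subject_id=rec.subject_id,
            domain_scores={d: float(scores[i, j])
                           for j, d in enumerate(DOMAINS)},
            composite=float(composite[i])))
    return out


def simulate_cohort(
    config: SimulationConfig | None = None,
    layout: NetworkLayout | None = None,
) -> Cohort:
    """Generate a full cohort (EC truth, posteriors, covariates, cognition).

    Timeseries are not materialized here; call :func:`simulate_timeseries`
    per subject/network (or :func:`write_cohort` with
    ``with_timeseries=True``) when they are needed.
    """
    config = config or SimulationConfig()
    layout = layout or make_layout()
    records, truth = simulate_true_ec(layout, config)
    posteriors = make_ec_posteriors(records, layout, config)
    cognition = simulate_cognition(records, layout, config)
    truth.update({
        "planted_rho": config.planted_rho,
        "planted_x_idx": list(config.planted_x_idx),
        "planted_y_idx": list(config.planted_y_idx),
    })
    return Cohort(layout=layout, config=config, records=records,
                  posteriors=posteriors, cognition=cognition, truth=truth)


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 with_timeseries: bool = False) -> None:
    """Write a cohort to a directory in plain-text formats.

    Files: ``layout.json``, ``subjects.csv``, ``ec_posterior.csv`` (long
    format), ``cognition.csv``, ``truth.json`` and, optionally, one
    timeseries TSV per subject and network under ``timeseries/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "layout.json").write_text(cohort.layout.to_json())
    cohort.covariate_table().to_csv(out / "subjects.csv", index=False)
    cohort.cognition_table().to_csv(out / "cognition.csv", index=False)

    rows = []
    for post in cohort.posteriors:
        for net, labels in cohort.layout.networks:
            m, v = post.means[net], post.variances[net]
            for t, tgt in enumerate(labels):
                for s, src in enumerate(labels):
                    rows.append((post.subject_id, net, src, tgt,
                                 m[t, s], v[t, s]))
    pd.DataFrame(rows, columns=["subject_id", "network", "source", "target",
                                "mean", "variance"]
                 ).to_csv(out / "ec_posterior.csv", index=False)

    cfg = dataclasses.asdict(cohort.config)
    truth = dict(cohort.truth)
    truth["config"] = cfg
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    if with_timeseries:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(cohort.records):
            for k, net in enumerate(cohort.layout.network_names):
                rng = np.random.default_rng(
                    np.random.SeedSequence([cohort.config.seed, 31, i, k]))
                ts = simulate_timeseries(rec, net, cohort.config, rng)
                np.savetxt(ts_dir / f"{rec.subject_id}_{net}.tsv", ts,
                           delimiter="\t")


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Ground-truth EC is not reconstructed (only the posterior summaries and
    tables the pipeline consumes); records carry covariates with empty
    ``true_ec``.
    """
    src = Path(in_dir)
    layout = NetworkLayout.from_json((src / "layout.json").read_text())
    truth = json.loads((src / "truth.json").read_text())
    config = SimulationConfig(**truth.pop("config"))
    subjects = pd.read_csv(src / "subjects.csv")
    records = [SubjectRecord(subject_id=r.subject_id, group=r.group,
                             age=r.age, gender=r.gender,
                             medication=r.medication, true_ec={})
               for r in subjects.itertuples()]

    ec = pd.read_csv(src / "ec_posterior.csv")
    posteriors = []
    label_index = {net: {lab: i for i, lab in enumerate(labels)}
                   for net, labels in layout.networks}
    for sid, sub in ec.groupby("subject_id", sort=False):
        means = {net: np.zeros((len(labels), len(labels)))
                 for net, labels in layout.networks}
        variances = {net: np.zeros_like(m) for net, m in means.items()}
        for row in sub.itertuples():
            li = label_index[row.network]
            t, s = li[row.target], li[row.source]
            means[row.network][t, s] = row.mean
            variances[row.network][t, s] = row.variance
        posteriors.append(ECPosterior(subject_id=sid, means=means,
                                      variances=variances))
    order = {r.subject_id: i for i, r in enumerate(records)}
    posteriors.sort(key=lambda p: order[p.subject_id])

    cog = pd.read_csv(src / "cognition.csv")
    cognition = [CognitiveScores(
        subject_id=r.subject_id,
        domain_scores={d: getattr(r, d) for d in DOMAINS},
        composite=r.composite) for r in cog.itertuples()]
    return Cohort(layout=layout, config=config, records=records,
                  posteriors=posteriors, cognition=cognition, truth=truth)
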