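"""Seeded synthetic datasets with the shape of the competition data.

The competition dataset (1,974 training compounds with 729 precomputed
molecular descriptors, of which 225 are identically zero; pIC50 activity
labels; five binary ADMET labels; 50 unlabeled test compounds) has no
public accession, so the pipeline is exercised on synthetic data that
reproduces its shape and enough of its statistical structure for every
stage to have real work to do:

* descriptor columns are independent uniform or log-normal draws on
  heterogeneous scales, so min-max normalization matters;
* a small set of "signal" descriptors drives pIC50 through a linear map
  plus one pairwise product term (a smooth interaction linear models
  cannot represent exactly), plus Gaussian assay noise;
* a handful of deliberately collinear column pairs (monotone transforms,
  |Spearman rho| > 0.9) gives the redundancy filter something to remove;
* each ADMET label is drawn Bernoulli(sigmoid(linear score)) from its own
  descriptor subset, which partially overlaps the activity signal so the
  assembled decision space contains duplicates.

Compound identifiers are opaque SMILES-like strings ("CMPD_000001"); no
chemistry is implied.  All randomness flows from the single integer seed
in :class:`GeneratorConfig` through one generator stream, so identical
configurations yield bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ADMET_COLUMNS = ["Caco-2", "CYP3A4", "hERG", "HOB", "MN"]
ID_COLUMN = "SMILES"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Defaults mirror the competition dataset: 1,974 training compounds,
    50 test compounds, 729 descriptors with 225 all-zero columns.
    ``noise_sd`` is the standard deviation of additive Gaussian noise on
    pIC50 (log10 units; 0.3 is a typical assay reproducibility figure).
    ``label_coef_scale`` scales the logistic coefficients of the five
    ADMET label maps (larger = more separable labels) and
    ``label_intercepts`` shifts their logits, controlling prevalence.
    """

    n_train: int = 1974
    n_test: int = 50
    n_descriptors: int = 729
    n_zero_cols: int = 225
    n_signal: int = 10
    noise_sd: float = 0.3
    label_coef_scale: float = 2.0
    label_intercepts: tuple[float, float, float, float, float] = (0.0,) * 5
    n_collinear_pairs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_train": self.n_train, "n_test": self.n_test,
            "n_descriptors": self.n_descriptors, "n_zero_cols": self.n_zero_cols,
            "n_signal": self.n_signal, "n_collinear_pairs": self.n_collinear_pairs,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_train < 1 or self.n_descriptors < 1:
            raise ValueError("n_train and n_descriptors must be >= 1")
        if self.n_zero_cols + self.n_signal > self.n_descriptors:
            raise ValueError(
                f"n_zero_cols + n_signal = {self.n_zero_cols + self.n_signal} "
                f"exceeds n_descriptors = {self.n_descriptors}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.label_intercepts) != 5:
            raise ValueError("label_intercepts must have five entries")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset (for recovery tests).

    The activity function is
    ``pic50 = intercept + sum_i coef_i * x_i + gamma * x_a * x_b``
    over the raw values of the signal descriptors, where (a, b) are the
    first two signal columns.  Each ADMET property has a logistic map
    ``P(label=1) = sigmoid(intercept_p + coef_p . z_p)`` over standardized
    values of its own column subset.
    """

    signal_names: list[str]
    activity_coefs: np.ndarray
    activity_intercept: float
    interaction_pair: tuple[str, str]
    interaction_coef: float
    label_names: dict[str, list[str]] = field(default_factory=dict)
    label_coefs: dict[str, np.ndarray] = field(default_factory=dict)
    label_intercepts: dict[str, float] = field(default_factory=dict)
    label_means: dict[str, np.ndarray] = field(default_factory=dict)
    label_sds: dict[str, np.ndarray] = field(default_factory=dict)

    def activity(self, descriptors: pd.DataFrame) -> np.ndarray:
        """Evaluate the noiseless activity function on raw descriptor rows."""
        X = descriptors[self.signal_names].to_numpy(dtype=float)
        a, b = self.interaction_pair
        prod = descriptors[a].to_numpy(dtype=float) * descriptors[b].to_numpy(dtype=float)
        return self.activity_intercept + X @ self.activity_coefs + self.interaction_coef * prod

    def label_logits(self, prop: str, descriptors: pd.DataFrame) -> np.ndarray:
        """Logit of P(label=1) for one ADMET property on raw descriptor rows."""
        Z = descriptors[self.label_names[prop]].to_numpy(dtype=float)
        Z = (Z - self.label_means[prop]) / self.label_sds[prop]
        return self.label_intercepts[prop] + Z @ self.label_coefs[prop]


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    descriptors: pd.DataFrame       # train compounds x descriptors, raw scale
    activity: pd.DataFrame          # SMILES, IC50_nM, pIC50
    admet: pd.DataFrame             # SMILES + five binary columns
    test_descriptors: pd.DataFrame  # test compounds x descriptors
    truth: GroundTruth
    config: GeneratorConfig


def _compound_ids(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}_{i:06d}" for i in range(start, start + n)]


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one synthetic dataset from the configured distribution.

    Deterministic for a fixed config (including seed).  The returned
    descriptor tables are indexed by compound id with descriptor names as
    columns; exactly ``config.n_zero_cols`` columns are identically zero.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_descriptors
    names = [f"MD_{j:04d}" for j in range(1, p + 1)]

    perm = rng.permutation(p)
    zero_idx = np.sort(perm[: cfg.n_zero_cols])
    live_idx = np.sort(perm[cfg.n_zero_cols:])
    signal_idx = np.sort(rng.choice(live_idx, size=cfg.n_signal, replace=False))
    signal_set = set(signal_idx.tolist())
    other_idx = np.array([j for j in live_idx if j not in signal_set], dtype=int)

    n_total = cfg.n_train + cfg.n_test
    X = np.zeros((n_total, p))

    # Signal columns: Uniform(0, 1) so the activity optimum sits at a known
    # corner of the signal subspace and normalization is near-identity.
    for j in signal_idx:
        X[:, j] = rng.uniform(0.0, 1.0, n_total)

    # Remaining live columns: heterogeneous-scale uniform or log-normal.
    for j in other_idx:
        if rng.uniform() < 0.5:
            lo = rng.uniform(-5.0, 5.0)
            span = rng.uniform(0.5, 50.0)
            X[:, j] = rng.uniform(lo, lo + span, n_total)
        else:
            mu = rng.uniform(-1.0, 2.0)
            sigma = rng.uniform(0.3, 1.0)
            X[:, j] = rng.lognormal(mu, sigma, n_total)

    # Collinear pairs: overwrite some non-signal columns with near-affine
    # copies of other columns (small noise keeps them distinct but
    # |Spearman| stays > 0.9, and their curve shape — hence grey
    # relational rank — tracks the source).  The first few shadow signal
    # columns so the redundancy filter is exercised on activity-relevant
    # features too.
    n_pairs = min(cfg.n_collinear_pairs, other_idx.size // 2)
    pair_targets = other_idx[:n_pairs] if n_pairs else np.array([], dtype=int)
    n_signal_shadow = min(3, cfg.n_signal, n_pairs)
    sources: list[int] = list(signal_idx[:n_signal_shadow])
    pool = other_idx[n_pairs:]
    for k in range(n_pairs - n_signal_shadow):
        sources.append(int(pool[k % max(pool.size, 1)]) if pool.size else int(signal_idx[0]))
    collinear_pairs: list[tuple[int, int]] = []
    for tgt, src in zip(pair_targets, sources):
        s = X[:, src]
        # rank-jittered permutation of the source's own values: identical
        # marginal distribution (so normalization treats both alike) with
        # slightly perturbed ordering, giving |Spearman| > 0.9 while the
        # curve similarity to any reference is honestly degraded
        ranks = np.argsort(np.argsort(s))
        jitter = rng.uniform(0.0, 0.15 * n_total, n_total)
        new_rank = np.argsort(np.argsort(ranks + jitter))
        shadow = np.sort(s)[new_rank]
        scale = rng.uniform(0.5, 2.0)
        X[:, tgt] = scale * shadow + rng.uniform(-1.0, 1.0)
        collinear_pairs.append((int(src), int(tgt)))

    signal_names = [names[j] for j in signal_idx]
    coefs = rng.uniform(0.2, 0.6, cfg.n_signal)
    gamma = float(rng.uniform(1.5, 2.5)) if cfg.n_signal >= 2 else 0.0
    intercept = 5.0
    pair_names = (signal_names[0], signal_names[1] if cfg.n_signal >= 2 else signal_names[0])

    truth = GroundTruth(
        signal_names=signal_names,
        activity_coefs=coefs,
        activity_intercept=intercept,
        interaction_pair=pair_names,
        interaction_coef=gamma,
    )

    all_ids = _compound_ids("CMPD", n_total)
    full = pd.DataFrame(X, index=pd.Index(all_ids, name=ID_COLUMN), columns=names)
    train = full.iloc[: cfg.n_train]
    test = full.iloc[cfg.n_train:]

    pic50_clean = truth.activity(train)
    pic50 = pic50_clean + rng.normal(0.0, cfg.noise_sd, cfg.n_train)
    ic50 = pic50_to_ic50_array(pic50)
    activity = pd.DataFrame(
        {"IC50_nM": ic50, "pIC50": pic50},
        index=train.index.copy(),
    )

    # ADMET label maps: per property, a logistic score over a small column
    # subset (two signal columns + four other live columns).  hERG and MN
    # coefficients are independent draws like every other property; no
    # property inherits the activity coefficients or their signs.
    admet = {}
    n_sub_signal = min(2, cfg.n_signal)
    n_sub_other = min(4, other_idx.size)
    for prop, b0 in zip(ADMET_COLUMNS, cfg.label_intercepts):
        sub_sig = rng.choice(signal_idx, size=n_sub_signal, replace=False) if n_sub_signal else np.array([], dtype=int)
        sub_oth = rng.choice(other_idx, size=n_sub_other, replace=False) if n_sub_other else np.array([], dtype=int)
        sub = np.concatenate([sub_sig, sub_oth]).astype(int)
        sub_names = [names[j] for j in sub]
        w = cfg.label_coef_scale * rng.uniform(0.5, 1.5, sub.size)
        w *= rng.choice([-1.0, 1.0], size=sub.size)
        mu = train[sub_names].to_numpy().mean(axis=0)
        sd = train[sub_names].to_numpy().std(axis=0)
        sd[sd == 0] = 1.0
        truth.label_names[prop] = sub_names
        truth.label_coefs[prop] = w
        truth.label_intercepts[prop] = float(b0)
        truth.label_means[prop] = mu
        truth.label_sds[prop] = sd
        logits = truth.label_logits(prop, train)
        probs = 1.0 / (1.0 + np.exp(-logits))
        admet[prop] = (rng.uniform(size=cfg.n_train) < probs).astype(int)
    admet_df = pd.DataFrame(admet, index=train.index.copy())

    return SyntheticDataset(
        descriptors=train, activity=activity, admet=admet_df,
        test_descriptors=test, truth=truth, config=cfg,
    )


def pic50_to_ic50_array(pic50: np.ndarray) -> np.ndarray:
    # local to avoid an import cycle with the activity module
    return np.power(10.0, 9.0 - np.asarray(pic50, dtype=float))


def prevalence_report(admet: pd.DataFrame) -> dict[str, float]:
    """Fraction of positive labels per ADMET property.

    Raises on an empty table; each fraction lies in [0, 1].
    """
    if len(admet) == 0:
        raise ValueError("ADMET table is empty")
    cols = [c for c in admet.columns if c in ADMET_COLUMNS]
    if not cols:
        raise ValueError("ADMET table has no recognized property columns")
    return {c: float(admet[c].mean()) for c in cols}


def write_dataset(data: SyntheticDataset, outdir: str | Path, xlsx: bool = False) -> dict[str, Path]:
    """Write the three training tables and the test descriptor table.

    CSV with a header row and the compound id in a first column named
    "SMILES", matching the layout of the source files.  Set ``xlsx`` to
    additionally emit .xlsx copies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "Molecular_Descriptor.csv": data.descriptors,
        "ERa_activity.csv": data.activity,
        "ADMET.csv": data.admet,
        "Molecular_Descriptor_test.csv": data.test_descriptors,
    }
    written: dict[str, Path] = {}
    for fname, df in tables.items():
        path = outdir / fname
        df.reset_index().to_csv(path, index=False)
        written[fname] = path
        if xlsx:
            xpath = path.with_suffix(".xlsx")
            df.reset_index().to_excel(xpath, index=False)
            written[xpath.name] = xpath
    return written


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["label_intercepts"] = list(d["label_intercepts"])
    return d
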