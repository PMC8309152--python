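"""Synthetic solubility-study generator.

Emulates the statistical structure of a literature-curated intrinsic
solubility training set and of the two SC-2-style evaluation sets so that
every downstream stage (curation, feature selection, network training,
metrics, applicability domain) can be exercised without any external data:

* per-molecule true logS0 drawn from a Gaussian with mean -3.4 and SD 1.95
  log units (the curated-training-set moments);
* a replicate-count histogram matching the study's (189 singletons, 50
  duplicates, ... one molecule with 10 sources; 270 molecules, 412 values);
* inter-laboratory replicate noise with average SD 0.78 log units, emitted
  in a 50/50 mixture of log-molar and ug/mL records to exercise unit
  conversion;
* ten named descriptors whose population correlations with logS0 match the
  study's selected-descriptor profile (ALOGP -0.637 down to Hy -0.138),
  generated from a single latent factor: descriptor_j = rho_j * z +
  sqrt(1 - rho_j^2) * eps_j with z the standardised logS0;
* a 100-compound low-variance "tight" test set (inter-lab SD 0.17, mean
  -4.03, SD 1.27) and a 32-compound high-variance "loose" set (SD 0.62,
  mean -5.49, SD 2.18), the latter with a configurable fraction of
  compounds shifted outside the training descriptor cloud;
* experimental logP / melting-point surrogates for the general solubility
  equation baseline.

The latent-factor descriptor model implies pairwise descriptor correlations
rho_i * rho_j; a full descriptor-descriptor correlation matrix can be
injected via ``correlation_matrix`` to test the pruning rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TABLE_REPLICATE_HISTOGRAM",
    "DEFAULT_DESCRIPTOR_CORRELATIONS",
    "TestSetSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "gen_true_solubilities",
    "gen_replicate_records",
    "gen_descriptors",
    "gen_test_sets",
    "gen_gse_inputs",
    "generate_study",
]

#: replicate-count histogram of the curated training set:
#: {replicates per molecule: number of molecules}; 270 molecules, 412 values.
TABLE_REPLICATE_HISTOGRAM: dict[int, int] = {
    1: 189, 2: 50, 3: 18, 4: 7, 5: 1, 6: 3, 8: 1, 10: 1,
}

#: target correlation of each selected descriptor with logS0.
DEFAULT_DESCRIPTOR_CORRELATIONS: dict[str, float] = {
    "ALOGP": -0.637,  # Ghose-Crippen octanol-water partition coefficient
    "nC": -0.583,     # number of carbon atoms
    "nCIC": -0.511,   # number of rings
    "nBnz": -0.510,   # number of benzene-like rings
    "Ui": -0.434,     # unsaturation index
    "Me": 0.310,      # mean atomic Sanderson electronegativity
    "RBN": -0.224,    # number of rotatable bonds
    "nN": 0.214,      # number of nitrogen atoms
    "nX": -0.200,     # number of halogens
    "Hy": -0.138,     # hydrophilic factor
}

# plausible (location, scale, count-like) profile per descriptor; affine maps
# leave correlations untouched, they only set readable magnitudes.
_DESCRIPTOR_PROFILES: dict[str, tuple[float, float, bool]] = {
    "ALOGP": (2.3, 1.8, False),
    "nC": (18.0, 7.0, True),
    "nCIC": (3.0, 1.6, True),
    "nBnz": (1.3, 1.0, True),
    "Ui": (2.8, 1.2, False),
    "Me": (0.95, 0.08, False),
    "RBN": (5.0, 3.2, True),
    "nN": (2.2, 1.7, True),
    "nX": (0.8, 1.4, True),
    "Hy": (0.3, 1.1, False),
}


def descriptor_profile(name: str) -> tuple[float, float, bool]:
    return _DESCRIPTOR_PROFILES.get(name, (0.0, 1.0, False))


@dataclass
class TestSetSpec:
    """Moments and noise level of one evaluation set."""

    n: int
    interlab_sd: float
    mean: float
    sd: float
    #: fraction of compounds whose descriptors are shifted out of the
    #: training cloud (emulating sparsely populated chemical space)
    shift_fraction: float = 0.0
    #: shift size in per-descriptor scale units
    shift_magnitude: float = 4.0


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults are the stated ones."""

    n_molecules: int = 270
    target_mean: float = -3.4
    target_sd: float = 1.95
    replicate_histogram: dict[int, int] = field(
        default_factory=lambda: dict(TABLE_REPLICATE_HISTOGRAM))
    interlab_sd: float = 0.78
    descriptor_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_CORRELATIONS))
    test_tight: TestSetSpec = field(
        default_factory=lambda: TestSetSpec(n=100, interlab_sd=0.17, mean=-4.03, sd=1.27))
    test_loose: TestSetSpec = field(
        default_factory=lambda: TestSetSpec(n=32, interlab_sd=0.62, mean=-5.49, sd=2.18,
                                            shift_fraction=3 / 32))
    gse_logp_correlation: float = -0.8
    integerize_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.target_sd < 0 or self.interlab_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.replicate_histogram:
            raise ValueError("replicate histogram must be non-empty")
        for name, rho in self.descriptor_correlations.items():
            if not abs(rho) < 1:
                raise ValueError(f"|correlation| must be < 1 for {name}")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named deterministic sub-streams derived from the one seed."""
        names = ["truths", "replicates", "descriptors", "tight", "loose", "gse"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def gen_true_solubilities(config: SyntheticConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-molecule true logS0 from Normal(target_mean, target_sd^2)."""
    config.validate()
    rng = rng or config.streams()["truths"]
    return rng.normal(config.target_mean, config.target_sd, size=config.n_molecules)


def _c4(n: int) -> float:
    """Unbiasing constant of the sample SD: E[s] = c4(n) * sigma for Gaussian data."""
    if n < 2:
        return 1.0
    from scipy.special import gammaln
    return float(np.sqrt(2.0 / (n - 1)) *
                 np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0)))


def _replicate_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    hist = config.replicate_histogram
    ks = np.array(sorted(hist), dtype=int)
    counts = np.array([hist[int(k)] for k in ks], dtype=int)
    if counts.sum() == config.n_molecules:
        # exact histogram, randomly assigned to molecules
        assignment = np.repeat(ks, counts)
        return rng.permutation(assignment)
    # otherwise draw counts from the histogram proportions
    p = counts / counts.sum()
    return rng.choice(ks, size=config.n_molecules, p=p)


def gen_replicate_records(true_values: np.ndarray, config: SyntheticConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit one raw record per replicate, in mixed units.

    Each molecule receives a replicate count drawn from the configured
    histogram (exactly the histogram when its counts sum to ``n_molecules``)
    and each replicate is the true value plus Gaussian inter-laboratory
    noise.  The noise scale for a molecule with n >= 2 replicates is
    ``interlab_sd / c4(n)`` so that the mean of per-molecule *sample*
    standard deviations — the statistic the curation summary reports — is
    an unbiased estimate of the configured inter-laboratory SD.  Records
    are emitted 50/50 in log-molar or ug/mL (with a synthetic molecular
    weight uniform in [100, 600] g/mol) to exercise unit conversion
    downstream.
    """
    rng = rng or config.streams()["replicates"]
    counts = _replicate_counts(config, rng)
    rows = []
    for i, (mu, k) in enumerate(zip(true_values, counts)):
        cid = f"MOL{i:04d}"
        mw = rng.uniform(100.0, 600.0)
        sigma = config.interlab_sd / _c4(int(k))
        noisy = mu + rng.normal(0.0, sigma, size=int(k))
        for j, logv in enumerate(noisy):
            use_mass = rng.random() < 0.5
            if use_mass:
                # molar -> g/L -> ug/mL  (1 g/L = 1000 ug/mL)
                value = 10.0 ** logv * mw * 1e3
                unit = "ug_per_mL"
            else:
                value, unit = logv, "log_molar"
            rows.append({"compound_id": cid, "cas": cid, "source_id": f"lab{j:02d}",
                         "value": value, "unit": unit, "mw": mw, "polymorph": ""})
    return pd.DataFrame(rows)


def gen_descriptors(true_values: np.ndarray,
                    correlations: Mapping[str, float],
                    rng: np.random.Generator,
                    integerize: bool = False,
                    correlation_matrix: np.ndarray | None = None,
                    center: float | None = None,
                    scale: float | None = None) -> pd.DataFrame:
    """Latent-factor descriptor table with prescribed target correlations.

    ``descriptor_j = rho_j * z + sqrt(1 - rho_j^2) * eps_j`` with ``z`` the
    standardised true logS0, then affine-mapped to a plausible range per
    descriptor name.  ``center``/``scale`` fix the standardisation (pass
    the *training* population moments so training and test compounds share
    one descriptor space); by default the sample moments are used.  With
    ``correlation_matrix`` the residuals ``eps`` are drawn jointly Gaussian
    with that correlation instead of independently (the target
    correlations are then approximate), which lets tests build strongly
    collinear descriptor pairs.
    """
    true_values = np.asarray(true_values, dtype=float)
    n = len(true_values)
    center = true_values.mean() if center is None else float(center)
    scale = true_values.std() if scale is None else float(scale)
    z = np.zeros(n) if scale == 0 else (true_values - center) / scale
    names = list(correlations)
    m = len(names)
    if correlation_matrix is not None:
        corr = np.asarray(correlation_matrix, dtype=float)
        if corr.shape != (m, m):
            raise ValueError("correlation_matrix shape must match descriptor count")
        chol = np.linalg.cholesky(corr)
        eps = rng.standard_normal((n, m)) @ chol.T
    else:
        eps = rng.standard_normal((n, m))
    out = {}
    for j, name in enumerate(names):
        rho = float(correlations[name])
        raw = rho * z + np.sqrt(1.0 - rho * rho) * eps[:, j]
        loc, scale, count_like = descriptor_profile(name)
        col = loc + scale * raw
        if integerize and count_like:
            col = np.clip(np.rint(col), 0, None)
        out[name] = col
    return pd.DataFrame(out)


def _gen_one_test_set(spec: TestSetSpec, config: SyntheticConfig,
                      rng: np.random.Generator, prefix: str) -> pd.DataFrame:
    true = rng.normal(spec.mean, spec.sd, size=spec.n)
    observed = true + rng.normal(0.0, spec.interlab_sd, size=spec.n)
    # standardise by the *training* moments: test compounds live in the same
    # descriptor space as the training cloud
    desc = gen_descriptors(true, config.descriptor_correlations, rng,
                           integerize=config.integerize_counts,
                           center=config.target_mean, scale=config.target_sd)
    shifted = np.zeros(spec.n, dtype=bool)
    if spec.shift_fraction > 0:
        k = int(round(spec.shift_fraction * spec.n))
        idx = rng.choice(spec.n, size=k, replace=False)
        shifted[idx] = True
        for name in desc.columns:
            _, scale, _ = descriptor_profile(name)
            signs = rng.choice([-1.0, 1.0], size=k)
            desc.loc[idx, name] += signs * spec.shift_magnitude * scale
    table = pd.DataFrame({
        "compound_id": [f"{prefix}{i:03d}" for i in range(spec.n)],
        "logS0": observed,
        "true_logS0": true,
        "shifted": shifted,
    })
    return pd.concat([table, desc], axis=1)


def gen_test_sets(config: SyntheticConfig,
                  rng_tight: np.random.Generator | None = None,
                  rng_loose: np.random.Generator | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the tight (low-variance) and loose (high-variance) test sets."""
    config.validate()
    streams = None
    if rng_tight is None or rng_loose is None:
        streams = config.streams()
    rng_tight = rng_tight or streams["tight"]
    rng_loose = rng_loose or streams["loose"]
    tight = _gen_one_test_set(config.test_tight, config, rng_tight, "TST1-")
    loose = _gen_one_test_set(config.test_loose, config, rng_loose, "TST2-")
    return tight, loose


def gen_gse_inputs(true_values: np.ndarray, config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   compound_ids: list[str] | None = None) -> pd.DataFrame:
    """Surrogate experimental logP and Celsius melting point per compound.

    The melting point is Normal(150, 50^2) degC truncated at 25 degC.  logP
    is drawn with the configured correlation to logS0 (latent construction,
    as for the descriptors) but located and scaled so that the general
    solubility equation is unbiased on average — i.e. logP scatters around
    the GSE-inverse 0.5 - logS0 - 0.001 (Tmp_mean - 25), as it does for
    real drug-like compounds.  At |rho| = 1 the relation is exact up to the
    melting-point term.
    """
    rng = rng or config.streams()["gse"]
    true_values = np.asarray(true_values, dtype=float)
    n = len(true_values)
    rho = float(config.gse_logp_correlation)
    sd = config.target_sd
    z = np.zeros(n) if sd == 0 else (true_values - config.target_mean) / sd
    raw = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    a = (25.0 - 150.0) / 50.0
    tmp_mean = float(stats.truncnorm.mean(a, np.inf, loc=150.0, scale=50.0))
    loc = 0.5 - config.target_mean - 0.001 * (tmp_mean - 25.0)
    # -sd/rho makes the regression slope of logP on logS0 exactly -1, the
    # GSE slope, while preserving corr(logP, logS0) = rho
    scale = -sd / rho if rho != 0 else sd
    logp = loc + scale * raw
    tmp = stats.truncnorm.rvs(a, np.inf, loc=150.0, scale=50.0, size=n, random_state=rng)
    if compound_ids is None:
        compound_ids = [f"MOL{i:04d}" for i in range(n)]
    return pd.DataFrame({"compound_id": compound_ids, "logP": logp, "Tmp": tmp})


@dataclass
class SyntheticStudy:
    """Everything one synthetic study run produces."""

    config: SyntheticConfig
    true_logS0: pd.DataFrame          # compound_id, true_logS0
    records: pd.DataFrame             # raw replicate records, mixed units
    descriptors: pd.DataFrame         # compound_id x descriptor columns
    test_tight: pd.DataFrame
    test_loose: pd.DataFrame
    gse_train: pd.DataFrame           # compound_id, logP, Tmp
    gse_tight: pd.DataFrame
    gse_loose: pd.DataFrame

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["replicate_histogram"] = {str(k): v for k, v in
                                      self.config.replicate_histogram.items()}
        return {"config": cfg,
                "n_records": int(len(self.records)),
                "n_molecules": int(self.true_logS0.shape[0])}

    def write(self, outdir) -> None:
        """Write all tables as headered CSV plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.descriptors.to_csv(outdir / "descriptors.csv", index=False)
        self.true_logS0.to_csv(outdir / "true_logS0.csv", index=False)
        self.test_tight.to_csv(outdir / "test_tight.csv", index=False)
        self.test_loose.to_csv(outdir / "test_loose.csv", index=False)
        self.gse_train.to_csv(outdir / "gse_train.csv", index=False)
        self.gse_tight.to_csv(outdir / "gse_tight.csv", index=False)
        self.gse_loose.to_csv(outdir / "gse_loose.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def generate_study(config: SyntheticConfig | None = None, seed: int | None = None
                   ) -> SyntheticStudy:
    """Generate a full synthetic study (records, descriptors, test sets, GSE)."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    streams = config.streams()
    true = gen_true_solubilities(config, streams["truths"])
    ids = [f"MOL{i:04d}" for i in range(config.n_molecules)]
    records = gen_replicate_records(true, config, streams["replicates"])
    desc = gen_descriptors(true, config.descriptor_correlations,
                           streams["descriptors"], integerize=config.integerize_counts,
                           center=config.target_mean, scale=config.target_sd)
    descriptors = pd.concat([pd.DataFrame({"compound_id": ids}), desc], axis=1)
    tight, loose = gen_test_sets(config, streams["tight"], streams["loose"])
    gse_rng = streams["gse"]
    gse_train = gen_gse_inputs(true, config, gse_rng, ids)
    gse_tight = gen_gse_inputs(tight["true_logS0"].to_numpy(), config, gse_rng,
                               list(tight["compound_id"]))
    gse_loose = gen_gse_inputs(loose["true_logS0"].to_numpy(), config, gse_rng,
                               list(loose["compound_id"]))
    return SyntheticStudy(config=config,
                          true_logS0=pd.DataFrame({"compound_id": ids, "true_logS0": true}),
                          records=records, descriptors=descriptors,
                          test_tight=tight, test_loose=loose,
                          gse_train=gse_train, gse_tight=gse_tight, gse_loose=gse_loose)
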