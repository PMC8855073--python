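"""Seeded negative-binomial count simulation for a four-group factorial knockout design.

The generator emulates a study with two knockout-vs-control contrasts measured
in separate mouse lines:

* contrast A — a double-receptor knockout vs its floxed control
  (``koA`` vs ``controlA``), with the downstream transcription factors intact;
* contrast B — a quintuple knockout vs a triple-knockout control
  (``koB`` vs ``controlB``), i.e. the same receptor loss on a background where
  the downstream factors are already deleted.

Genes are planted in three classes. *Dependent* genes respond in contrast A
and have their contrast-B response attenuated (by default to zero): the
downstream factor mediates the response. *Independent* genes respond with the
same sign in both contrasts. *Null* genes have no effect in either contrast.
Counts are negative-binomial with a mean/dispersion parameterization
(variance ``mu + phi * mu**2``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("controlA", "koA", "controlB", "koB")

#: distribution spec: ("uniform", low, high) on the given scale,
#: ("uniform_signed", low, high) for a uniform magnitude with a random sign,
#: or ("normal", loc, scale).
DistSpec = tuple


def _draw(spec: DistSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if kind == "uniform_signed":
        mags = rng.uniform(spec[1], spec[2], size)
        signs = rng.choice([-1.0, 1.0], size)
        return mags * signs
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size)
    raise ValueError(f"unknown distribution spec kind: {kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_genes, n_per_group
        Number of genes and biological replicates per genotype group
        (four groups in total).
    frac_dependent, frac_independent
        Proportions of planted dependent / independent genes; the remainder
        are null. Must sum to at most 1.
    effect_log2fc_A
        Distribution of planted contrast-A log2 fold changes for non-null
        genes. Default: magnitude uniform on [1, 3] with a random sign.
    attenuation_B
        Multiplier in [0, 1) applied to the contrast-A effect to obtain the
        contrast-B effect of *dependent* genes (0 = fully mediated).
    independent_jitter
        Half-width of a multiplicative uniform jitter on the contrast-B
        effect of *independent* genes (0 = identical effect in both
        contrasts). Must be < 1 so the sign is preserved.
    baseline_log2_mean
        Distribution of baseline log2 relative abundance per gene.
    dispersion
        Constant NB dispersion phi (variance = mu + phi mu^2); 0 gives
        Poisson counts.
    library_size
        Expected total counts per sample before size-factor variation.
    size_factor_sigma
        Log-normal sigma of per-sample size factors (0 disables depth
        variation).
    seed
        Seed for all randomness in the dataset.
    """

    n_genes: int = 10_000
    n_per_group: int = 6
    groups: tuple = GROUPS
    frac_dependent: float = 0.2
    frac_independent: float = 0.05
    effect_log2fc_A: DistSpec = ("uniform_signed", 1.0, 3.0)
    attenuation_B: float = 0.0
    independent_jitter: float = 0.0
    baseline_log2_mean: DistSpec = ("normal", 5.0, 2.0)
    dispersion: float = 0.1
    library_size: float = 5e6
    size_factor_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ValueError("n_genes and n_per_group must be positive")
        if len(self.groups) != 4:
            raise ValueError("exactly four group labels are required")
        if not (0 <= self.frac_dependent <= 1 and 0 <= self.frac_independent <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_dependent + self.frac_independent > 1:
            raise ValueError("frac_dependent + frac_independent must be <= 1")
        if not 0 <= self.attenuation_B < 1:
            raise ValueError("attenuation_B must lie in [0, 1)")
        if not 0 <= self.independent_jitter < 1:
            raise ValueError("independent_jitter must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass
class SyntheticDataset:
    """Counts, sample metadata and planted truth of one simulation."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    metadata: pd.DataFrame  # sample_id, group
    truth: pd.DataFrame  # gene_id index; label, true_log2fc_A, true_log2fc_B
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict:
        """Write counts/metadata/truth as TSV; return the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
        return {k: str(v) for k, v in paths.items()}


def nb_sample(
    mu: np.ndarray | float, phi: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray:
    """Draw negative-binomial counts with mean ``mu`` and variance ``mu + phi*mu**2``.

    ``phi = 0`` degenerates to Poisson, ``mu = 0`` returns 0 with probability
    one. In the size/probability parameterization this is
    ``NB(n = 1/phi, p = 1/(1 + phi*mu))``.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be nonnegative")
    if np.any(phi < 0):
        raise ValueError("phi must be nonnegative")
    mu_b, phi_b = np.broadcast_arrays(mu, phi)
    out = np.zeros(mu_b.shape, dtype=np.int64)
    pois = phi_b == 0
    if np.any(pois):
        out[pois] = rng.poisson(mu_b[pois])
    nb = ~pois
    if np.any(nb):
        size = 1.0 / phi_b[nb]
        p = size / (size + mu_b[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out if out.ndim else out[()]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a seeded four-group dataset with planted truth labels.

    Label counts are deterministic: ``round(frac * n_genes)`` dependent and
    independent genes, the remainder null. Group means are
    ``baseline * 2**true_log2fc`` in the knockout group of each contrast.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_dep = round(config.frac_dependent * n)
    n_ind = round(config.frac_independent * n)

    labels = np.array(
        ["dependent"] * n_dep + ["independent"] * n_ind + ["null"] * (n - n_dep - n_ind)
    )
    lfc_a = np.zeros(n)
    lfc_b = np.zeros(n)
    planted = n_dep + n_ind
    lfc_a[:planted] = _draw(config.effect_log2fc_A, planted, rng)
    lfc_b[:n_dep] = config.attenuation_B * lfc_a[:n_dep]
    jit = 1.0 + rng.uniform(
        -config.independent_jitter, config.independent_jitter, n_ind
    )
    lfc_b[n_dep:planted] = lfc_a[n_dep:planted] * jit

    width = len(str(n))
    gene_ids = [f"gene{i:0{width}d}" for i in range(1, n + 1)]
    truth = pd.DataFrame(
        {"label": labels, "true_log2fc_A": lfc_a, "true_log2fc_B": lfc_b},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    baseline = 2.0 ** _draw(config.baseline_log2_mean, n, rng)
    rel = baseline / baseline.sum()

    sample_ids, sample_groups = [], []
    for g in config.groups:
        for r in range(1, config.n_per_group + 1):
            sample_ids.append(f"{g}_{r}")
            sample_groups.append(g)
    n_samples = len(sample_ids)
    size_factors = np.exp(rng.normal(0.0, config.size_factor_sigma, n_samples))

    group_lfc = {
        config.groups[0]: np.zeros(n),
        config.groups[1]: lfc_a,
        config.groups[2]: np.zeros(n),
        config.groups[3]: lfc_b,
    }
    mu = np.empty((n, n_samples))
    for j, (sid, grp) in enumerate(zip(sample_ids, sample_groups)):
        mu[:, j] = rel * config.library_size * size_factors[j] * 2.0 ** group_lfc[grp]

    counts = nb_sample(mu, config.dispersion, rng)
    counts_df = pd.DataFrame(
        counts, index=truth.index, columns=pd.Index(sample_ids, name="sample_id")
    )
    metadata = pd.DataFrame({"sample_id": sample_ids, "group": sample_groups})
    return SyntheticDataset(counts=counts_df, metadata=metadata, truth=truth, config=config)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. a TOML section)."""
    kwargs = {}
    for f in dataclasses.fields(SimulationConfig):
        if f.name in d:
            v = d[f.name]
            if f.name in ("effect_log2fc_A", "baseline_log2_mean", "groups"):
                v = tuple(v)
            kwargs[f.name] = v
    return SimulationConfig(**kwargs)
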