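"""Synthetic study generator: every input the pipeline consumes.

The generator emulates a genus-scale comparative study of genome size:

* an ultrametric pure-birth (Yule) phylogeny;
* a genome-size trait evolved on that tree under BM, Pagel's-lambda, or OU
  dynamics, scaled to a plausible large-genome range (2C about 45-170 pg,
  basic number x = 12);
* environmental covariates built as a linear function of the trait plus a
  Brownian residual on the same tree, so PGLS assumptions hold exactly;
* per-species karyotypes (log-normal chromosome lengths, Beta-distributed
  centromeric indices) calibrated to target CV_CL / CV_CI / mean CI;
* two-peak flow-cytometry histograms (sample + internal-standard G1 peaks,
  Gaussian with stated CV, multinomial event counts over an exponential
  debris floor).

Reproducibility: every generator is a pure function of its configuration and
seed.  ``make_study_bundle`` derives one independent child seed per
operation from the master seed via :class:`numpy.random.SeedSequence`
spawning, so adding a generator never perturbs the streams of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .flowcyto import FlowHistogram
from .karyotype import Karyotype, normalize_karyotype, summarize_karyotype
from .tree import Phylogeny, bm_covariance, lambda_transform

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm",
    "simulate_lambda_trait",
    "simulate_ou",
    "simulate_environment",
    "simulate_karyotype",
    "simulate_flow_histogram",
    "make_study_bundle",
]


@dataclass
class SimulationConfig:
    """Study-level configuration for :func:`make_study_bundle`.

    Defaults describe a genus-scale design: 71 species on a Yule tree, a
    strongly heritable genome-size trait (lambda = 0.6), environment
    covariates linearly coupled to genome size, diploid karyotypes with
    x = 12, and paired flow-cytometry runs of 10,000 events at 3% peak CV
    against an internal standard of 2C = 30.9 pg.
    """

    seed: int = 42
    n_tips: int = 71
    birth_rate: float = 1.0

    # genome-size trait (on the 2C pg scale)
    trait_model: str = "LAMBDA"  # one of BM, LAMBDA, OU
    sigma2: float = 1.0
    lam: float = 0.6
    alpha: float = 1.0
    theta: float = 0.0
    root_state: float = 0.0
    gs_low: float = 45.0   # 2C pg, lower end of the rescaled trait
    gs_high: float = 170.0

    # environment regression: env = intercept + slope * trait + BM noise
    env_slope: float = 1.5
    env_intercept: float = 0.0
    env_noise_sigma2: float = 1.0

    # karyotype targets
    x: int = 12
    ploidy: int = 2
    mean_chrom_len: float = 8.0  # micrometres
    cv_cl_target: float = 25.0
    mean_ci: float = 30.0
    cv_ci_target: float = 30.0

    # flow-cytometry histograms
    standard_2c_pg: float = 30.9
    standard_channel: float = 120.0
    n_channels: int = 1024
    events: int = 10000
    peak_cv: float = 3.0
    debris_fraction: float = 0.05
    histograms_per_species: int = 2

    n_regions: int = 4
    region_names: tuple = (
        "MountainHighlands",
        "FarEast",
        "WestTemperate",
        "NewWorld",
    )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> Phylogeny:
    """Ultrametric pure-birth tree with tips labelled sp001, sp002, ...

    Standard Yule construction: starting from a single lineage, each of the
    ``k`` live lineages splits after an Exp(k * birth_rate) wait; tips are
    cut at the moment the (n_tips)-th lineage appears, making the tree
    ultrametric.  Tip labels follow the left-to-right order of the final
    tree.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    live = [root]
    birth_time = {root: 0.0}
    t = 0.0
    while len(live) < n_tips:
        k = len(live)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        parent = live.pop(idx)
        parent.edge.length = t - birth_time[parent]
        for _ in range(2):
            child = parent.new_child()
            birth_time[child] = t
            live.append(child)
    # final waiting time to the present
    k = len(live)
    t += rng.exponential(1.0 / (k * birth_rate))
    for leaf in live:
        leaf.edge.length = t - birth_time[leaf]
    root.edge.length = None

    width = max(3, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    return Phylogeny(tree)


def _preorder_nodes(tree: Phylogeny):
    return list(tree._tree.preorder_node_iter())


def simulate_bm(
    tree: Phylogeny, sigma2: float, root_state: float = 0.0, seed=0
) -> pd.Series:
    """Brownian-motion trait: child = parent + Normal(0, sigma2 * branch length)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng(seed)
    values: dict = {}
    for node in _preorder_nodes(tree):
        if node.parent_node is None:
            values[node] = float(root_state)
        else:
            bl = node.edge.length
            values[node] = values[node.parent_node] + rng.normal(
                0.0, math.sqrt(sigma2 * bl) if sigma2 * bl > 0 else 0.0
            )
    return pd.Series(
        {leaf.taxon.label: values[leaf] for leaf in tree._tree.leaf_node_iter()},
        name="bm_trait",
    )


def simulate_lambda_trait(
    tree: Phylogeny, lam: float, sigma2: float, root_state: float = 0.0, seed=0
) -> pd.Series:
    """Trait with Pagel's-lambda covariance: one multivariate-normal draw."""
    rng = _rng(seed)
    C = lambda_transform(bm_covariance(tree), lam)
    n = len(C.tip_order)
    L = np.linalg.cholesky(sigma2 * C.matrix + 1e-12 * np.eye(n))
    y = root_state + L @ rng.standard_normal(n)
    return pd.Series(y, index=C.tip_order, name="lambda_trait")


def simulate_ou(
    tree: Phylogeny,
    alpha: float,
    theta: float,
    sigma2: float,
    root_state: float = 0.0,
    seed=0,
) -> pd.Series:
    """Ornstein-Uhlenbeck trait by exact branch-wise transition sampling.

    Along a branch of length t the trait moves from the parent value v to
    ``v e^{-alpha t} + theta (1 - e^{-alpha t})`` plus Gaussian noise with
    variance ``sigma2 (1 - e^{-2 alpha t}) / (2 alpha)``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = _rng(seed)
    values: dict = {}
    for node in _preorder_nodes(tree):
        if node.parent_node is None:
            values[node] = float(root_state)
        else:
            t = node.edge.length
            decay = math.exp(-alpha * t)
            mean = values[node.parent_node] * decay + theta * (1.0 - decay)
            var = sigma2 * (1.0 - decay**2) / (2.0 * alpha)
            values[node] = mean + rng.normal(0.0, math.sqrt(var) if var > 0 else 0.0)
    return pd.Series(
        {leaf.taxon.label: values[leaf] for leaf in tree._tree.leaf_node_iter()},
        name="ou_trait",
    )


def simulate_environment(
    trait: pd.Series,
    slope: float,
    intercept: float,
    tree: Phylogeny,
    phylo_noise_sigma2: float,
    seed=0,
) -> pd.Series:
    """Covariate linearly coupled to a trait with Brownian phylogenetic residual.

    ``env = intercept + slope * trait + BM(0, phylo_noise_sigma2)`` on the
    same tree, so a PGLS of ``env`` on ``trait`` under BM satisfies its own
    assumptions exactly with true slope ``slope``.
    """
    noise = simulate_bm(tree, phylo_noise_sigma2, root_state=0.0, seed=seed)
    env = intercept + slope * trait.reindex(noise.index) + noise
    env.name = "environment"
    return env


def simulate_karyotype(
    x: int,
    mean_len: float,
    cv_cl_target: float,
    mean_ci: float,
    cv_ci_target: float,
    seed=0,
    species: str = "",
    ploidy: int = 2,
) -> Karyotype:
    """Karyotype with chromosome lengths and centromeric indices near targets.

    Lengths are log-normal, moment-matched to (mean_len, cv_cl_target in %);
    centromeric indices are Beta on (0, 50], moment-matched to
    (mean_ci, cv_ci_target in %).  Zero CV targets yield identical
    chromosomes.  Arms are ``short = len * CI/100`` and ``long = len - short``.
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    if not (0 < mean_ci <= 50):
        raise ValueError("mean CI must be in (0, 50]")
    rng = _rng(seed)

    cv_l = cv_cl_target / 100.0
    if cv_l == 0:
        lengths = np.full(x, mean_len)
    else:
        s2 = math.log1p(cv_l**2)
        mu = math.log(mean_len) - s2 / 2.0
        lengths = rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=x)

    cv_c = cv_ci_target / 100.0
    if cv_c == 0:
        cis = np.full(x, mean_ci)
    else:
        m = mean_ci / 50.0  # Beta mean on (0, 1)
        v = (mean_ci * cv_c / 50.0) ** 2
        v = min(v, 0.99 * m * (1.0 - m))  # keep Beta parameters positive
        common = m * (1.0 - m) / v - 1.0
        a, b = m * common, (1.0 - m) * common
        cis = 50.0 * rng.beta(a, b, size=x)
        cis = np.clip(cis, 1e-6, 50.0)

    raw = []
    for L, ci in zip(lengths, cis):
        short = L * ci / 100.0
        raw.append((short, L - short))
    return normalize_karyotype(raw, x=x, ploidy=ploidy, species=species)


def simulate_flow_histogram(
    true_2c_pg: float,
    standard_2c_pg: float = 30.9,
    standard_channel: float = 120.0,
    n_channels: int = 1024,
    events: int = 10000,
    peak_cv: float = 3.0,
    debris_fraction: float = 0.05,
    seed=0,
    sample_label: str = "",
    standard_label: str = "internal_standard",
) -> FlowHistogram:
    """Two-peak Gaussian histogram with an exponential debris floor.

    The standard G1 peak sits at ``standard_channel``; the sample G1 peak at
    ``standard_channel * true_2c / standard_2c`` (fluorescence-DNA
    linearity).  Events are split multinomially between the two peaks (after
    removing the debris fraction), each Gaussian with the stated CV; debris
    decays exponentially from channel 0.
    """
    if true_2c_pg <= 0 or standard_2c_pg <= 0:
        raise ValueError("2C values must be positive")
    if not (0 <= debris_fraction < 1):
        raise ValueError("debris fraction must be in [0, 1)")
    rng = _rng(seed)
    channels = np.arange(n_channels)
    sample_channel = standard_channel * true_2c_pg / standard_2c_pg
    if sample_channel >= n_channels - 10:
        raise ValueError("sample peak falls outside the channel range")

    def gauss_pmf(mu: float) -> np.ndarray:
        sig = mu * peak_cv / 100.0
        p = np.exp(-0.5 * ((channels - mu) / sig) ** 2)
        return p / p.sum()

    debris = np.exp(-channels / (0.15 * n_channels))
    debris /= debris.sum()
    p = (
        debris_fraction * debris
        + (1.0 - debris_fraction) * 0.5 * gauss_pmf(sample_channel)
        + (1.0 - debris_fraction) * 0.5 * gauss_pmf(standard_channel)
    )
    counts = rng.multinomial(events, p)
    return FlowHistogram(
        channels=channels,
        counts=counts,
        sample_label=sample_label,
        standard_label=standard_label,
    )


def _rescale(values: pd.Series, low: float, high: float) -> pd.Series:
    span = values.max() - values.min()
    if span == 0:
        return pd.Series(np.full(len(values), (low + high) / 2.0), index=values.index)
    return low + (values - values.min()) / span * (high - low)


def make_study_bundle(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> dict:
    """Generate a complete synthetic comparative study.

    Returns a dict with the tree, trait table, karyotypes, histograms and a
    truth ledger (true lambda/slopes/2C values) for recovery tests; when
    ``out_dir`` is given everything is also written to disk in the formats
    the pipeline reads (Newick, TSV, histogram CSVs).
    """
    master = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: s
        for name, s in zip(
            ["tree", "trait", "temp", "precip", "elev", "karyo", "hist"],
            master.spawn(7),
        )
    }

    tree = simulate_yule_tree(cfg.n_tips, cfg.birth_rate, seed=seeds["tree"])

    if cfg.trait_model == "BM":
        raw = simulate_bm(tree, cfg.sigma2, cfg.root_state, seed=seeds["trait"])
    elif cfg.trait_model == "LAMBDA":
        raw = simulate_lambda_trait(
            tree, cfg.lam, cfg.sigma2, cfg.root_state, seed=seeds["trait"]
        )
    elif cfg.trait_model == "OU":
        raw = simulate_ou(
            tree, cfg.alpha, cfg.theta, cfg.sigma2, cfg.root_state, seed=seeds["trait"]
        )
    else:
        raise ValueError(f"unknown trait model {cfg.trait_model!r}")

    two_c = _rescale(raw, cfg.gs_low, cfg.gs_high)
    one_cx = two_c / cfg.ploidy

    # environment covariates coupled to 1Cx; elevation anti-correlated
    temp = simulate_environment(
        one_cx, cfg.env_slope, cfg.env_intercept, tree, cfg.env_noise_sigma2,
        seed=seeds["temp"],
    )
    precip = simulate_environment(
        one_cx, cfg.env_slope * 20.0, 400.0, tree,
        cfg.env_noise_sigma2 * 400.0, seed=seeds["precip"],
    )
    elev = simulate_environment(
        one_cx, -30.0, 4000.0, tree, cfg.env_noise_sigma2 * 900.0,
        seed=seeds["elev"],
    )

    # regions and sections: contiguous tip blocks (clade-like labels)
    labels = tree.tip_labels
    n = len(labels)
    region_of = {}
    section_of = {}
    n_regions = min(cfg.n_regions, len(cfg.region_names))
    for i, sp in enumerate(labels):
        region_of[sp] = cfg.region_names[min(i * n_regions // n, n_regions - 1)]
        section_of[sp] = f"sect{(i * 6 // n) + 1}"

    karyo_seeds = seeds["karyo"].spawn(n)
    karyotypes: dict[str, Karyotype] = {}
    for sp, ks in zip(labels, karyo_seeds):
        # HCL tracks genome size: mean chromosome length proportional to 1Cx
        mean_len = cfg.mean_chrom_len * float(one_cx[sp]) / float(one_cx.mean())
        karyotypes[sp] = simulate_karyotype(
            cfg.x,
            mean_len,
            cfg.cv_cl_target,
            cfg.mean_ci,
            cfg.cv_ci_target,
            seed=ks,
            species=sp,
            ploidy=cfg.ploidy,
        )

    hist_seeds = seeds["hist"].spawn(n * cfg.histograms_per_species)
    histograms: dict[str, list[FlowHistogram]] = {}
    for i, sp in enumerate(labels):
        reps = []
        for r in range(cfg.histograms_per_species):
            reps.append(
                simulate_flow_histogram(
                    true_2c_pg=float(two_c[sp]),
                    standard_2c_pg=cfg.standard_2c_pg,
                    standard_channel=cfg.standard_channel,
                    n_channels=cfg.n_channels,
                    events=cfg.events,
                    peak_cv=cfg.peak_cv,
                    debris_fraction=cfg.debris_fraction,
                    seed=hist_seeds[i * cfg.histograms_per_species + r],
                    sample_label=sp,
                )
            )
        histograms[sp] = reps

    metrics = {sp: summarize_karyotype(k) for sp, k in karyotypes.items()}
    traits = pd.DataFrame(
        {
            "species": labels,
            "two_c_pg": [round(float(two_c[sp]), 4) for sp in labels],
            "ploidy": cfg.ploidy,
            "one_cx_pg": [
                round(float(two_c[sp]) / cfg.ploidy, 4) for sp in labels
            ],
            "HCL": [round(metrics[sp].hcl, 4) for sp in labels],
            "AsK_pct": [round(metrics[sp].ask_percent, 4) for sp in labels],
            "CV_CI": [round(metrics[sp].cv_ci, 4) for sp in labels],
            "CV_CL": [round(metrics[sp].cv_cl, 4) for sp in labels],
            "x": cfg.x,
            "two_n": cfg.x * cfg.ploidy,
            "elevation_m": [round(float(elev[sp]), 1) for sp in labels],
            "annual_mean_temp_c": [round(float(temp[sp]), 3) for sp in labels],
            "annual_precip_mm": [round(float(precip[sp]), 1) for sp in labels],
            "region": [region_of[sp] for sp in labels],
            "section": [section_of[sp] for sp in labels],
        }
    )

    truth = {
        "trait_model": cfg.trait_model,
        "lambda": cfg.lam if cfg.trait_model == "LAMBDA" else None,
        "sigma2": cfg.sigma2,
        "alpha": cfg.alpha if cfg.trait_model == "OU" else None,
        "env_slope_temp": cfg.env_slope,
        "env_slope_precip": cfg.env_slope * 20.0,
        "env_slope_elev": -30.0,
        "standard_2c_pg": cfg.standard_2c_pg,
        "true_two_c": {sp: float(two_c[sp]) for sp in labels},
    }

    bundle = {
        "tree": tree,
        "traits": traits,
        "karyotypes": karyotypes,
        "histograms": histograms,
        "truth": truth,
        "config": cfg,
    }

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tree: Phylogeny = bundle["tree"]
    (out / "tree.nwk").write_text(tree.to_newick())
    bundle["traits"].to_csv(out / "traits.tsv", sep="\t", index=False)

    rows = []
    for sp, k in bundle["karyotypes"].items():
        for ci, (short, long) in enumerate(k.chromosomes, start=1):
            rows.append(
                {
                    "species": sp,
                    "chromosome_id": ci,
                    "short_arm_um": round(short, 4),
                    "long_arm_um": round(long, 4),
                    "x": k.x,
                    "ploidy": k.ploidy,
                }
            )
    pd.DataFrame(rows).to_csv(out / "karyotypes.tsv", sep="\t", index=False)

    hist_dir = out / "histograms"
    hist_dir.mkdir(exist_ok=True)
    for sp, reps in bundle["histograms"].items():
        for r, hist in enumerate(reps, start=1):
            hist.to_csv(hist_dir / f"{sp}_rep{r}.csv")

    truth = bundle["truth"]
    scalar = {k: v for k, v in truth.items() if not isinstance(v, dict)}
    pd.DataFrame([scalar]).to_csv(out / "truth_scalars.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "species": list(truth["true_two_c"]),
            "true_two_c_pg": list(truth["true_two_c"].values()),
        }
    ).to_csv(out / "truth_two_c.tsv", sep="\t", index=False)
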