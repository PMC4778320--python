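"""Synthetic isoform-level cohorts with planted, registered events.

The generator emulates the statistical structure the switching analysis
assumes, so every pipeline stage can be exercised and scored against a known
truth without external data:

* per-gene isoform counts follow a simple/complex mix (most genes express
  one or two isoforms);
* isoforms of a gene share the gene's per-sample abundance noise through
  fixed Dirichlet usage proportions, so within-gene pairs are predominantly
  positively correlated;
* RNA degradation inflates the *shortest* isoform of designated genes in
  proportion to (rin_max - RIN), creating artifact "switches";
* subtype switches flip a pair's usage between one intrinsic subtype and the
  rest while the gene total stays fixed (the CTNND1-like pattern);
* bimodal switches flip usage by a latent per-sample Bernoulli state that is
  independent of subtype (the PRICKLE1-like pattern);
* signature genes gain expression proportional to the latent log2 usage
  ratio of the first bimodal pair, giving SAM a planted gene signature.

Counts are log-normal: gene log2 abundance = gene mean + N(0, noise_sd),
split by usage proportions, with per-isoform log2 noise and a per-sample
library-depth factor that upper-quartile normalization must undo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    SUBTYPES,
    IsoformCatalog,
    IsoformMatrix,
    IsoswitchError,
    SampleAnnotation,
    write_annotation,
    write_catalog,
    write_isoform_matrix,
)

Pair = tuple[str, str]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's reference cohort."""

    n_samples: int = 300
    normal_fraction: float = 0.11
    subtype_proportions: dict = field(
        default_factory=lambda: {
            "Basal": 0.18,
            "Her2": 0.08,
            "LumA": 0.40,
            "LumB": 0.22,
            "NormalLike": 0.12,
        }
    )
    n_genes: int = 2000
    #: probability of a gene expressing 1, 2, or 3+ isoforms
    isoform_count_distribution: dict = field(
        default_factory=lambda: {1: 0.43, 2: 0.24, 3: 0.33}
    )
    #: conditional distribution of the count for "3+" genes
    extra_isoform_distribution: dict = field(
        default_factory=lambda: {3: 0.50, 4: 0.30, 5: 0.15, 6: 0.05}
    )
    base_log_expression: tuple = (6.0, 1.5)  # (mean, sd) of gene log2 abundance
    isoform_proportion_concentration: float = 3.0
    #: RIN model: most samples come from an intact stratum (scaled Beta on
    #: ``rin_range``, left-skewed so RINs concentrate near the top), while a
    #: ``degraded_fraction`` of tumors forms a degraded stratum with uniform
    #: RIN on ``degraded_rin_range``; normal tissues are always intact
    rin_range: tuple = (7.0, 10.0)
    rin_beta: tuple = (3.0, 1.0)
    degraded_fraction: float = 0.15
    degraded_rin_range: tuple = (2.0, 5.5)
    degradation_effect: float = 0.5  # log2 inflation of the shortest isoform per RIN unit lost
    n_rin_artifacts: int = 30
    n_subtype_switches: int = 50
    switch_effect_delta: float = 2.5  # log2-ratio shift between subtype groups
    n_bimodal_switches: int = 10
    bimodal_mixing: float = 0.4
    bimodal_effect_delta: float = 3.0
    n_signature_genes: int = 300
    signature_slope: tuple = (0.5, 0.05)
    noise_sd: float = 0.2  # per-sample gene-level log2 noise (shared by isoforms)
    isoform_noise_sd: float = 0.3  # per-sample per-isoform log2 noise
    depth_sd: float = 0.3  # per-sample log2 library-depth jitter
    seed: int = 17

    def validate(self) -> None:
        if self.n_samples < 4:
            raise IsoswitchError("n_samples must be >= 4")
        for name in ("normal_fraction", "bimodal_mixing", "degraded_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise IsoswitchError(f"{name} must lie in [0, 1)")
        for name, dist in (
            ("subtype_proportions", self.subtype_proportions),
            ("isoform_count_distribution", self.isoform_count_distribution),
            ("extra_isoform_distribution", self.extra_isoform_distribution),
        ):
            vals = np.array(list(dist.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise IsoswitchError(f"{name} must be non-negative and sum to 1")
        n_planted = self.n_rin_artifacts + self.n_subtype_switches + self.n_bimodal_switches
        if n_planted + self.n_signature_genes > self.n_genes:
            raise IsoswitchError("n_genes too small for the requested planted events")
        if self.n_signature_genes > 0 and self.n_bimodal_switches == 0:
            raise IsoswitchError(
                "n_signature_genes > 0 requires n_bimodal_switches >= 1 (the driver pair)"
            )
        if self.degradation_effect < 0:
            raise IsoswitchError("degradation_effect must be >= 0")


@dataclass
class TruthRegistry:
    """Ground truth of planted events, keyed by (predominant, alternative) pairs."""

    rin_artifact_pairs: set[Pair] = field(default_factory=set)
    subtype_switch_pairs: dict[Pair, dict] = field(default_factory=dict)
    bimodal_pairs: dict[Pair, dict] = field(default_factory=dict)
    signature_genes: dict[str, float] = field(default_factory=dict)

    def driver_pair(self) -> Pair | None:
        """The bimodal pair whose latent ratio drives the gene signature."""
        return next(iter(sorted(self.bimodal_pairs)), None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rin_artifact_pairs": ["|".join(p) for p in sorted(self.rin_artifact_pairs)],
            "subtype_switch_pairs": {
                "|".join(p): v for p, v in sorted(self.subtype_switch_pairs.items())
            },
            "bimodal_pairs": {"|".join(p): v for p, v in sorted(self.bimodal_pairs.items())},
            "signature_genes": dict(sorted(self.signature_genes.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRegistry":
        payload = json.loads(Path(path).read_text())
        split = lambda s: tuple(s.split("|"))
        return cls(
            rin_artifact_pairs={split(p) for p in payload["rin_artifact_pairs"]},
            subtype_switch_pairs={split(p): v for p, v in payload["subtype_switch_pairs"].items()},
            bimodal_pairs={split(p): v for p, v in payload["bimodal_pairs"].items()},
            signature_genes=payload["signature_genes"],
        )


def simulate_cohort(
    config: SimConfig,
) -> tuple[IsoformMatrix, IsoformCatalog, SampleAnnotation, TruthRegistry]:
    """Generate a cohort with planted events under ``config`` (seeded, exact)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    # --- samples: tissue, subtype, RIN -----------------------------------
    n_normal = int(round(config.normal_fraction * n))
    is_normal = np.zeros(n, dtype=bool)
    is_normal[rng.choice(n, size=n_normal, replace=False)] = True
    subtype_names = list(config.subtype_proportions)
    subtype_p = np.array([config.subtype_proportions[s] for s in subtype_names])
    subtype = np.where(
        is_normal, "NA", rng.choice(subtype_names, size=n, p=subtype_p)
    )
    lo, hi = config.rin_range
    a, b = config.rin_beta
    rin = lo + (hi - lo) * rng.beta(a, b, size=n)
    # degraded stratum allocated proportionally within each subtype so that
    # specimen quality stays independent of subtype (as in the emulated
    # cohort, where degradation is a property of the specimen, not the tumor)
    dlo, dhi = config.degraded_rin_range
    degraded = np.zeros(n, dtype=bool)
    for st in subtype_names:
        idx = np.flatnonzero((subtype == st) & ~is_normal)
        k_deg = int(round(config.degraded_fraction * len(idx)))
        if k_deg:
            degraded[rng.choice(idx, size=k_deg, replace=False)] = True
    rin[degraded] = rng.uniform(dlo, dhi, size=int(degraded.sum()))

    annot = SampleAnnotation(
        frame=pd.DataFrame(
            {
                "tissue": np.where(is_normal, "normal", "tumor"),
                "subtype": subtype,
                "rin": rin,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    # --- planted roles ----------------------------------------------------
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted_n = config.n_rin_artifacts + config.n_subtype_switches + config.n_bimodal_switches
    chosen = rng.choice(config.n_genes, size=planted_n + config.n_signature_genes, replace=False)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in chosen[cursor : cursor + k]]
        cursor += k
        return out

    artifact_genes = take(config.n_rin_artifacts)
    subtype_genes = take(config.n_subtype_switches)
    bimodal_genes = take(config.n_bimodal_switches)
    signature_gene_ids = take(config.n_signature_genes)
    pair_genes = set(artifact_genes) | set(subtype_genes) | set(bimodal_genes)

    # --- gene/isoform structure ------------------------------------------
    count_keys = sorted(config.isoform_count_distribution)
    count_p = np.array([config.isoform_count_distribution[k] for k in count_keys])
    extra_keys = sorted(config.extra_isoform_distribution)
    extra_p = np.array([config.extra_isoform_distribution[k] for k in extra_keys])
    mu_mean, mu_sd = config.base_log_expression
    mu_floor = mu_mean - 0.5 * mu_sd  # planted genes are well-expressed (CTNND1/PRICKLE1-like)

    truth = TruthRegistry()
    switch_subtypes = [SUBTYPES[i % len(SUBTYPES)] for i in range(config.n_subtype_switches)]
    latent_bimodal = {
        g: (rng.random(n) < config.bimodal_mixing).astype(int) for g in bimodal_genes
    }
    # slope magnitudes now; signs assigned after baseline expressions are
    # drawn (see below) so up- and down-correlated genes are matched by
    # expression level and the per-sample upper quartile stays composition-
    # stable — a signature contains both directions in comparable numbers
    slope_mean, slope_sd = config.signature_slope
    slope_magnitudes = {g: float(rng.normal(slope_mean, slope_sd)) for g in signature_gene_ids}

    iso_rows = []  # (isoform_id, gene_id, length)
    log2_values = []  # per-isoform vector of log2 abundance
    driver_latent_ratio: np.ndarray | None = None
    gene_mu: dict[str, float] = {}
    gene_noise: dict[str, np.ndarray] = {}
    signature_effects: dict[str, np.ndarray] = {}

    tumor_mask = ~is_normal

    for gene in genes:
        if gene in pair_genes:
            k = 2
        elif gene in slope_magnitudes:
            # single-isoform signature genes keep the mirror-pair cancellation
            # exact on the isoform scale, where the upper quartile is computed
            k = 1
        else:
            c = rng.choice(count_keys, p=count_p)
            k = int(c) if c < 3 else int(rng.choice(extra_keys, p=extra_p))
        lengths = np.round(np.exp(rng.uniform(np.log(500), np.log(10000), size=k))).astype(int)
        iso_ids = [f"{gene}.i{j + 1}" for j in range(k)]

        mu = float(rng.normal(mu_mean, mu_sd))
        if gene in pair_genes:
            mu = max(mu, mu_floor)
        gene_mu[gene] = mu
        noise = rng.normal(0.0, config.noise_sd, size=n)
        gene_noise[gene] = noise

        # usage proportions, shared across samples
        if gene in pair_genes:
            # predominant = the longer member at 60% usage; for artifact
            # genes the shorter member is the degradation target
            long_idx = int(np.argmax(lengths))
            shares = np.full(k, 0.4)
            shares[long_idx] = 0.6
            pred_idx, alt_idx = long_idx, 1 - long_idx
        else:
            shares = rng.dirichlet(np.full(k, config.isoform_proportion_concentration))
            shares = np.clip(shares, 1e-6, None)
            pred_idx = alt_idx = -1

        log2_shares = np.tile(np.log2(shares), (n, 1))  # samples x k

        if gene in artifact_genes:
            short_idx = int(np.argmin(lengths))
            log2_shares[:, short_idx] += config.degradation_effect * (hi - rin)
            truth.rin_artifact_pairs.add((iso_ids[pred_idx], iso_ids[alt_idx]))
        elif gene in subtype_genes:
            st = switch_subtypes[subtype_genes.index(gene)]
            in_group = (subtype == st) & tumor_mask
            d = config.switch_effect_delta
            # symmetric flip: the log2 usage ratio shifts by +d/2 in the
            # subtype group and -d/2 elsewhere (total separation d)
            sign = np.where(in_group, 1.0, -1.0)
            log2_shares[:, alt_idx] += sign * d / 4.0
            log2_shares[:, pred_idx] -= sign * d / 4.0
            truth.subtype_switch_pairs[(iso_ids[pred_idx], iso_ids[alt_idx])] = {
                "gene_id": gene,
                "subtype": st,
                "delta": d,
            }
        elif gene in bimodal_genes:
            z = latent_bimodal[gene]
            d = config.bimodal_effect_delta
            sign = np.where(z == 1, 1.0, -1.0)
            log2_shares[:, alt_idx] += sign * d / 4.0
            log2_shares[:, pred_idx] -= sign * d / 4.0
            truth.bimodal_pairs[(iso_ids[pred_idx], iso_ids[alt_idx])] = {
                "gene_id": gene,
                "delta": d,
                "assignment": {s: int(v) for s, v in zip(samples, z)},
            }
            latent_ratio = log2_shares[:, alt_idx] - log2_shares[:, pred_idx]
            if (iso_ids[pred_idx], iso_ids[alt_idx]) == sorted(
                truth.bimodal_pairs
            )[0]:
                driver_latent_ratio = latent_ratio

        # renormalize usage per sample; gene total is untouched by any flip
        w = np.power(2.0, log2_shares)
        w /= w.sum(axis=1, keepdims=True)

        for j, iso in enumerate(iso_ids):
            iso_rows.append((iso, gene, int(lengths[j])))
            log2_values.append((gene, np.log2(w[:, j])))

    # second pass: signature signs alternate along baseline expression so
    # that up- and down-shifted genes are locally balanced around every
    # expression level (including the upper quartile); effects use the
    # driver pair's latent usage ratio, centered
    if slope_magnitudes:
        if driver_latent_ratio is None:
            raise IsoswitchError("internal: driver latent ratio missing")
        centered = driver_latent_ratio - driver_latent_ratio.mean()
        by_expression = sorted(slope_magnitudes, key=lambda g: (gene_mu[g], g))
        for rank, g in enumerate(by_expression):
            sign = 1.0 if rank % 2 == 0 else -1.0
            # adjacent genes in the expression ranking form mirror pairs
            # (same magnitude, opposite sign) so the shifted mass crossing
            # any abundance quantile cancels
            partner = by_expression[rank - 1] if rank % 2 else g
            truth.signature_genes[g] = sign * slope_magnitudes[partner]
            signature_effects[g] = truth.signature_genes[g] * centered

    depth = rng.normal(0.0, config.depth_sd, size=n)
    iso_noise = rng.normal(
        0.0, config.isoform_noise_sd, size=(len(log2_values), n)
    )
    values = np.empty((len(log2_values), n))
    for idx, (gene, log2_share) in enumerate(log2_values):
        g_log2 = gene_mu[gene] + gene_noise[gene]
        if gene in signature_effects:
            g_log2 = g_log2 + signature_effects[gene]
        values[idx] = np.power(
            2.0, g_log2 + log2_share + iso_noise[idx] + depth
        )

    iso_index = pd.Index([r[0] for r in iso_rows], name="isoform_id")
    matrix = IsoformMatrix(
        values=pd.DataFrame(values, index=iso_index, columns=samples), scale="raw"
    )
    catalog = IsoformCatalog(
        frame=pd.DataFrame(
            {"gene_id": [r[1] for r in iso_rows], "length": [r[2] for r in iso_rows]},
            index=iso_index,
        )
    )
    return matrix, catalog, annot, truth


def write_cohort(
    matrix: IsoformMatrix,
    catalog: IsoformCatalog,
    annot: SampleAnnotation,
    truth: TruthRegistry,
    directory: str | Path,
) -> dict[str, Path]:
    """Emit matrix/catalog/annotation TSVs plus the truth JSON; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "catalog": directory / "catalog.tsv",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth.json",
    }
    write_isoform_matrix(matrix, paths["matrix"])
    write_catalog(catalog, paths["catalog"])
    write_annotation(annot, paths["annotation"])
    truth.to_json(paths["truth"])
    return paths


def config_from_dict(payload: dict) -> SimConfig:
    """Build a SimConfig from a flat mapping, rejecting unknown fields."""
    known = {f.name for f in SimConfig.__dataclass_fields__.values()}
    unknown = set(payload) - known
    if unknown:
        raise IsoswitchError(f"unknown SimConfig field(s): {sorted(unknown)}")
    fixed = dict(payload)
    for key in ("isoform_count_distribution", "extra_isoform_distribution"):
        if key in fixed:
            fixed[key] = {int(k): float(v) for k, v in fixed[key].items()}
    for key in ("base_log_expression", "rin_range", "rin_beta", "signature_slope"):
        if key in fixed:
            fixed[key] = tuple(fixed[key])
    return SimConfig(**fixed)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
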