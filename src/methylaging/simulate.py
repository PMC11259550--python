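"""Synthetic cohort generation.

Everything downstream of raw array processing operates on a normalised beta
matrix plus sample metadata; this module generates such inputs with the
statistical structure the analysis assumes, together with the ground truth
needed to score recovery:

* ages drawn uniformly over the cohort range (20-87 years by default);
* a minority of probes whose beta drifts linearly with age -- hypermethylating
  probes preferentially placed in CpG-island/TSS contexts and
  hypomethylating probes in open-sea contexts, with per-year slopes on the
  order of the 0.002/year effect-size gate used downstream;
* bimodal context-dependent baselines (islands low, open sea high), so the
  net effect of more hypo- than hyper-methylating probes is a decline in
  mean methylation and a rise in methylation entropy with age;
* optional age-correlated cell-composition confounding: a neutrophil
  fraction that rises with age drives a set of ground-truth-null probes,
  which an unadjusted per-site model will miscall;
* Gaussian beta-scale noise, clipped to [0, 1].

Expression matrices with planted anti-correlated probe-gene links, purified
cell-type reference panels, and motif-occurrence tables are generated by
companion functions so that the integration and deconvolution stages are
testable end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import BLOOD_CELL_TYPES, FEATURE_CLASSES, ISLAND_CLASSES

log = logging.getLogger(__name__)

# island-context sampling probabilities by probe class
_CONTEXT_PROBS = {
    "up": [0.70, 0.15, 0.05, 0.10],      # Island, Shore, Shelf, OpenSea
    "down": [0.08, 0.10, 0.12, 0.70],
    "null": [0.30, 0.20, 0.12, 0.38],
}
# feature-context probabilities (order = FEATURE_CLASSES)
_FEATURE_PROBS = {
    "up": [0.25, 0.20, 0.10, 0.08, 0.22, 0.02, 0.03, 0.10],
    "down": [0.03, 0.05, 0.05, 0.03, 0.38, 0.03, 0.08, 0.35],
    "null": [0.08, 0.10, 0.08, 0.05, 0.35, 0.03, 0.06, 0.25],
}
# context-dependent baseline Beta(a, b) parameters: islands hypomethylated,
# open sea hypermethylated, mirroring array bimodality
_BASELINE_AB = {
    "Island": (2.0, 10.0),
    "Shore": (3.0, 7.0),
    "Shelf": (6.0, 4.0),
    "OpenSea": (9.0, 3.0),
}

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class CohortSpec:
    """Parameters of a synthetic methylation cohort.

    Defaults describe the reference study conditions: 250 adults aged
    20-87, 2000 probes of which 5% hypermethylate and 10% hypomethylate
    with age at 0.002-0.008 beta/year, residual noise SD 0.03 on the beta
    scale, a per-sample biological-age offset with SD 4 years shared by
    all age-drifting probes (so clock error bottoms out at a few years,
    as in real cohorts), and age-correlated cell-mixture confounding.
    """

    n_samples: int = 250
    n_probes: int = 2000
    age_range: tuple[float, float] = (20.0, 87.0)
    frac_up: float = 0.05
    frac_down: float = 0.10
    slope_range: tuple[float, float] = (0.002, 0.008)
    noise_sd: float = 0.03
    bioage_sd: float = 4.0
    confound_cells: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_probes <= 0:
            raise ValueError("n_samples and n_probes must be positive")
        lo, hi = self.age_range
        if lo >= hi:
            raise ValueError("age_range lower bound must be below upper bound")
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must lie in [0, 1]")
        a, b = self.slope_range
        if not (0 < a <= b <= 0.02):
            raise ValueError("slope_range must lie within (0, 0.02]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bioage_sd < 0:
            raise ValueError("bioage_sd must be non-negative")


@dataclass
class GroundTruth:
    """Per-probe truth for a generated cohort.

    ``probes`` has one row per probe: true age slope (beta/year), class
    (up/down/null), genomic context, and whether the probe is driven by an
    age-correlated cell proportion rather than age itself.  ``links`` is
    filled in by :func:`generate_expression` with one row per planted
    probe-gene link (gene, probe, sign of regulation).
    """

    probes: pd.DataFrame
    links: pd.DataFrame | None = field(default=None)

    @property
    def nonnull(self) -> pd.Index:
        return self.probes.index[self.probes["cls"] != "null"]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _probe_ids(p: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(1, p + 1)]


def generate_cohort(
    spec: CohortSpec, ages: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (beta matrix, sample table, probe annotation, ground truth).

    ``ages`` overrides the uniform age draw (used to construct exact
    examples); its length must equal ``spec.n_samples``.  Identical specs
    (and ages) give bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_probes
    lo, hi = spec.age_range

    samples = _sample_ids(n)
    probes = _probe_ids(p)

    if ages is None:
        ages = rng.uniform(lo, hi, n)
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (n,):
            raise ValueError("ages override must have length n_samples")
    sex = rng.integers(0, 2, n)
    bmi = np.clip(rng.normal(23.5, 3.0, n), 16.0, 40.0)

    # probe classes
    n_up = int(round(spec.frac_up * p))
    n_down = int(round(spec.frac_down * p))
    cls = np.array(["null"] * p, dtype=object)
    perm = rng.permutation(p)
    cls[perm[:n_up]] = "up"
    cls[perm[n_up:n_up + n_down]] = "down"

    island = np.empty(p, dtype=object)
    feature = np.empty(p, dtype=object)
    for c in ("up", "down", "null"):
        mask = cls == c
        island[mask] = rng.choice(ISLAND_CLASSES, size=mask.sum(), p=_CONTEXT_PROBS[c])
        feature[mask] = rng.choice(FEATURE_CLASSES, size=mask.sum(), p=_FEATURE_PROBS[c])

    chrom = rng.choice(_CHROMS, size=p)
    position = rng.integers(1, 240_000_000, size=p)

    slope = np.zeros(p)
    a, b = spec.slope_range
    slope[cls == "up"] = rng.uniform(a, b, (cls == "up").sum())
    slope[cls == "down"] = -rng.uniform(a, b, (cls == "down").sum())

    # context-dependent baselines; age-drifting probes are anchored so the
    # trend moves toward the intermediate state (beta = 0.5) without
    # crossing it: age-related drift erodes polarised methylation, which
    # is what raises entropy with age while mean methylation falls
    baseline = np.empty(p)
    for icls, (ba, bb) in _BASELINE_AB.items():
        mask = island == icls
        baseline[mask] = rng.beta(ba, bb, mask.sum())
    span = (hi - lo) * np.abs(slope)
    baseline = np.where(cls == "up", np.minimum(baseline, 0.5 - span), baseline)
    baseline = np.where(cls == "down", np.maximum(baseline, 0.5 + span), baseline)
    baseline = np.clip(baseline, 0.02, 0.98)

    # cell proportions; neutrophil fraction rises and CD8T falls with age
    # when confounding is on
    base_props = np.array([0.10, 0.15, 0.07, 0.05, 0.08, 0.55])  # BLOOD_CELL_TYPES order
    raw = np.tile(base_props, (n, 1))
    raw += rng.normal(0.0, 0.015, raw.shape)
    if spec.confound_cells:
        raw[:, 5] += 0.0020 * (ages - lo) + rng.normal(0.0, 0.03, n) - 0.05
        raw[:, 0] += -0.0010 * (ages - lo) + rng.normal(0.0, 0.02, n) + 0.03
    raw = np.clip(raw, 0.005, None)
    props = raw / raw.sum(axis=1, keepdims=True)

    cell_driven = np.zeros(p, dtype=bool)
    cell_gamma = np.zeros(p)
    if spec.confound_cells:
        null_idx = np.flatnonzero(cls == "null")
        n_cell = min(len(null_idx), max(1, int(round(0.02 * p))))
        chosen = rng.choice(null_idx, size=n_cell, replace=False)
        cell_driven[chosen] = True
        cell_gamma[chosen] = rng.choice([-1.0, 1.0], n_cell) * rng.uniform(1.5, 2.5, n_cell)

    # small sex/BMI nuisance effects, planted on null-class probes only so
    # the age slope of non-null probes is exactly the planted one
    sex_eff = np.zeros(p)
    bmi_eff = np.zeros(p)
    null_mask = cls == "null"
    sex_pick = rng.random(p) < 0.05
    bmi_pick = rng.random(p) < 0.03
    sex_eff[null_mask & sex_pick] = rng.uniform(-0.04, 0.04, (null_mask & sex_pick).sum())
    bmi_eff[null_mask & bmi_pick] = rng.uniform(-0.004, 0.004, (null_mask & bmi_pick).sum())

    # systematic per-sample biological-age offset: every age-drifting probe
    # reads the same individual as older/younger than their chronological
    # age, which floors downstream clock error at a few years
    bio_delta = rng.normal(0.0, spec.bioage_sd, n) if spec.bioage_sd > 0 else np.zeros(n)

    neu_centered = props[:, 5] - props[:, 5].mean()
    beta = (
        baseline[:, None]
        + slope[:, None] * (ages + bio_delta - lo)[None, :]
        + (cell_gamma * cell_driven)[:, None] * neu_centered[None, :]
        + sex_eff[:, None] * sex[None, :]
        + bmi_eff[:, None] * (bmi - bmi.mean())[None, :]
    )
    if spec.noise_sd > 0:
        beta += rng.normal(0.0, spec.noise_sd, beta.shape)
    clipped = np.mean((beta < 0) | (beta > 1))
    if clipped > 0:
        log.info("generate_cohort: %.3f%% of beta values clipped to [0,1]", 100 * clipped)
    beta = np.clip(beta, 0.0, 1.0)

    beta_df = pd.DataFrame(beta, index=probes, columns=samples)
    beta_df.index.name = "probe_id"

    sample_df = pd.DataFrame(
        {"age": ages, "sex": sex, "bmi": bmi, "bio_offset": bio_delta},
        index=pd.Index(samples, name="sample_id"),
    )
    for j, ct in enumerate(BLOOD_CELL_TYPES):
        sample_df[ct] = props[:, j]

    annot = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "gene": [f"GENE{i:05d}" for i in range(1, p + 1)],
            "island_class": island,
            "feature_class": feature,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    annot["distal_flag"] = annot["feature_class"].eq("IGR")

    truth = GroundTruth(
        probes=pd.DataFrame(
            {
                "true_slope": slope,
                "cls": cls,
                "island_class": island,
                "feature_class": feature,
                "cell_driven": cell_driven,
            },
            index=pd.Index(probes, name="probe_id"),
        )
    )
    return beta_df, sample_df, annot, truth


def generate_expression(
    truth: GroundTruth,
    samples: pd.DataFrame,
    beta: pd.DataFrame,
    coupling: float = 0.8,
    n_links: int = 30,
    n_noise_genes: int = 200,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) with planted probe-gene links.

    ``n_links`` non-null probes are each linked to one gene whose
    expression is anti-correlated with the probe's beta (scaled by
    ``coupling``; hypermethylating probes repress, hypomethylating probes
    activate their target).  Remaining genes are pure noise.  Returns the
    expression matrix and a gene-metadata table (chromosome, position,
    linked probe, sign); linked genes are placed near their probe so the
    genomic candidate ranking can find them.  ``truth.links`` is populated.
    """
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    rng = np.random.default_rng(seed)
    nonnull = list(truth.nonnull)
    if coupling != 0 and len(nonnull) == 0:
        raise ValueError("cannot plant links: ground truth has no non-null probes")

    annot_chrom = truth.probes.index  # probe order reference
    n_links = min(n_links, len(nonnull))
    linked_probes = list(rng.choice(nonnull, size=n_links, replace=False)) if n_links else []

    cols = list(samples.index)
    rows, meta = [], []
    gene_no = 0
    for probe in linked_probes:
        gene_no += 1
        gid = f"LNK{gene_no:04d}"
        bvec = beta.loc[probe, cols].to_numpy(dtype=float)
        sd = bvec.std()
        z = (bvec - bvec.mean()) / (sd if sd > 0 else 1.0)
        expr = 5.0 - coupling * z + (rng.normal(0.0, noise_sd, len(cols)) if noise_sd > 0 else 0.0)
        rows.append((gid, expr))
        meta.append((gid, probe, -1))
    for i in range(n_noise_genes):
        gid = f"RND{i + 1:04d}"
        rows.append((gid, rng.normal(5.0, 1.0, len(cols))))
        meta.append((gid, "", 0))

    expr_df = pd.DataFrame(
        {gid: vals for gid, vals in rows}, index=pd.Index(cols, name="sample_id")
    ).T
    expr_df.index.name = "gene_id"

    # genomic placement on a synthetic shared chromosome (probe i sits at
    # (i+1) Mb, see shared_coordinates): linked genes land within 80 kb of
    # their probe so candidate ranking by distance can recover them; noise
    # genes are scattered uniformly
    gene_meta = pd.DataFrame(meta, columns=["gene_id", "linked_probe", "sign"]).set_index("gene_id")
    probe_pos = {pid: (i + 1) * 1_000_000 for i, pid in enumerate(annot_chrom)}
    pos_list, chrom_list = [], []
    for gid, row in gene_meta.iterrows():
        if row["linked_probe"]:
            pos_list.append(probe_pos[row["linked_probe"]] + int(rng.integers(-80_000, 80_000)))
            chrom_list.append("chrS")
        else:
            pos_list.append(int(rng.integers(1, 1_000_000 * (len(annot_chrom) + 1))))
            chrom_list.append("chrS")
    gene_meta["chromosome"] = chrom_list
    gene_meta["position"] = pos_list

    truth.links = pd.DataFrame(
        {
            "gene_id": [g for g, r in gene_meta.iterrows() if r["linked_probe"]],
            "probe_id": [r["linked_probe"] for _, r in gene_meta.iterrows() if r["linked_probe"]],
            "sign": -1,
        }
    )
    return expr_df, gene_meta


def shared_coordinates(truth: GroundTruth) -> pd.DataFrame:
    """Probe coordinates on the synthetic shared chromosome used by
    :func:`generate_expression` for gene placement (probe i at (i+1) Mb)."""
    probes = truth.probes.index
    return pd.DataFrame(
        {
            "chromosome": "chrS",
            "position": [(i + 1) * 1_000_000 for i in range(len(probes))],
        },
        index=probes,
    )


def generate_cell_reference(
    k_cell_types: int = 6,
    n_marker_probes: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference beta profiles (marker probes x cell types).

    Each cell type gets a block of markers where it is highly methylated
    (0.85) and the others are low (0.10); with ``k_cell_types=6`` the
    columns carry the six standard whole-blood labels.
    """
    if k_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_marker_probes < k_cell_types:
        raise ValueError("need at least one marker probe per cell type")
    rng = np.random.default_rng(seed)
    names = (
        list(BLOOD_CELL_TYPES)
        if k_cell_types == 6
        else [f"CellType{i + 1}" for i in range(k_cell_types)]
    )
    ref = np.full((n_marker_probes, k_cell_types), 0.10)
    block = n_marker_probes // k_cell_types
    for j in range(k_cell_types):
        hi = (j + 1) * block if j < k_cell_types - 1 else n_marker_probes
        ref[j * block:hi, j] = 0.85
    if noise_sd > 0:
        ref = np.clip(ref + rng.normal(0.0, noise_sd, ref.shape), 0.0, 1.0)
    return pd.DataFrame(
        ref,
        index=pd.Index([f"mk{i:04d}" for i in range(1, n_marker_probes + 1)], name="probe_id"),
        columns=names,
    )


def generate_motif_table(
    annot: pd.DataFrame,
    truth: GroundTruth,
    n_motifs: int = 30,
    n_enriched: int = 3,
    background_rate: float = 0.05,
    enriched_rate: float = 0.40,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic motif-occurrence table (long form: motif_id, probe_id).

    The first ``n_enriched`` motifs occur at ``enriched_rate`` in
    hypermethylating (up-class) probes and at ``background_rate``
    elsewhere; the rest occur uniformly at the background rate.
    """
    rng = np.random.default_rng(seed)
    probes = annot.index
    up = truth.probes["cls"].reindex(probes).eq("up").to_numpy()
    rows = []
    for m in range(n_motifs):
        mid = f"MOTIF{m + 1:03d}"
        rate = np.where(up & (m < n_enriched), enriched_rate, background_rate)
        hit = rng.random(len(probes)) < rate
        rows.extend((mid, pid) for pid in probes[hit])
    return pd.DataFrame(rows, columns=["motif_id", "probe_id"])


def write_cohort(
    out_dir: str | Path,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    annot: pd.DataFrame,
    truth: GroundTruth,
    float_format: str = "%.8g",
) -> dict[str, Path]:
    """Write cohort tables as TSV/CSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "samples": out / "samples.csv",
        "annotation": out / "probes.csv",
        "truth": out / "truth.csv",
    }
    beta.to_csv(paths["beta"], sep="\t", float_format=float_format)
    samples.to_csv(paths["samples"], float_format=float_format)
    annot.to_csv(paths["annotation"], float_format=float_format)
    truth.probes.to_csv(paths["truth"], float_format=float_format)
    if truth.links is not None:
        paths["links"] = out / "links.csv"
        truth.links.to_csv(paths["links"], index=False)
    return paths
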