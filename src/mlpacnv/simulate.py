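"""Synthetic MLPA cohorts: true CNV diplotypes and the peak tables they produce.

Real MLPA raw data are capillary electropherograms; none are publicly
deposited for pharmacogene CNV surveys, so downstream stages are tested
against a generative stand-in.  The signal law is chosen so that the
expected dosage quotient of a target probe equals copies/2, the quantity
the whole pipeline is built to recover:

    height = base_height * (total_copies / 2) * sample_scale * noise

where ``sample_scale`` is a per-sample global intensity factor and
``noise`` a per-peak multiplicative log-normal term (both mean 1, with
configurable coefficients of variation).  Reference probes behave as
2-copy targets.  Zero copies emit exactly zero signal — there is no
additive background by default, so the homozygous-deletion DQ class
(DQ = 0) is reachable.  Q-fragments scale inversely with the DNA
quantity (adequate by default, hence low), D-fragments sit at reference
level, and the X/Y fragments follow a per-sample simulated sex.

Cohorts can be drawn in two ways: from per-gene allele frequencies
(deletion / wild-type / duplication alleles paired at random, i.e.
Hardy-Weinberg random mating, genes independent), or directly from a
table of diplotype-label frequencies, either by multinomial sampling or
deterministically by largest-remainder apportionment of exact counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelDef

__all__ = [
    "AlleleFreqSpec",
    "SimConfig",
    "ALLELE_COPIES",
    "diplotype_label",
    "apportion",
    "simulate_cohort",
    "simulate_from_genotype_table",
    "peaks_from_truth",
    "reference_truth",
    "simulate_run",
    "calls_from_truth",
]

#: Copies contributed by each CNV allele.
ALLELE_COPIES = {"del": 0, "wt": 1, "dup": 2}

#: Canonical (unordered) diplotype labels, including the Del/Dup state
#: that carries two copies in total and is invisible to dosage assays.
GENOTYPE_TO_ALLELES = {
    "Del/Del": ("del", "del"),
    "Del/Wt": ("del", "wt"),
    "Wt/Wt": ("wt", "wt"),
    "Dup/Wt": ("dup", "wt"),
    "Dup/Dup": ("dup", "dup"),
    "Del/Dup": ("del", "dup"),
}


def diplotype_label(allele1: str, allele2: str) -> str:
    """Unordered diplotype label for a pair of CNV alleles."""
    pair = tuple(sorted((allele1, allele2)))
    for label, alleles in GENOTYPE_TO_ALLELES.items():
        if tuple(sorted(alleles)) == pair:
            return label
    raise ValueError(f"unknown allele pair ({allele1!r}, {allele2!r})")


@dataclass(frozen=True)
class AlleleFreqSpec:
    """Per-gene CNV allele frequencies on the (del, wt, dup) simplex."""

    gene: str
    p_del: float = 0.0
    p_dup: float = 0.0

    def __post_init__(self) -> None:
        if self.p_del < 0 or self.p_dup < 0:
            raise ValueError(f"{self.gene}: allele frequencies must be >= 0")
        if self.p_del + self.p_dup > 1 + 1e-12:
            raise ValueError(
                f"{self.gene}: p_del + p_dup = {self.p_del + self.p_dup:.4f} "
                "exceeds 1"
            )

    @property
    def p_wt(self) -> float:
        return 1.0 - self.p_del - self.p_dup


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated MLPA run.

    ``noise_cv`` is the coefficient of variation of the per-peak
    multiplicative noise and ``sample_scale_cv`` that of the per-sample
    intensity factor; both are log-normal with mean 1 and must stay
    below 1 for the parameterization to be well defined.  ``base_height``
    is the expected peak height (arbitrary fluorescence units) of a
    2-copy target in an average sample.  ``dna_quantity`` of 1 means
    adequate template; Q-fragment signal scales as 1/dna_quantity.
    """

    n_samples: int
    freqs: tuple[AlleleFreqSpec, ...] = ()
    noise_cv: float = 0.05
    sample_scale_cv: float = 0.10
    base_height: float = 1000.0
    seed: int = 0
    q_level: float = 0.10
    dna_quantity: float = 1.0
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", tuple(self.freqs))
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name in ("noise_cv", "sample_scale_cv"):
            cv = getattr(self, name)
            if not 0 <= cv < 1:
                raise ValueError(f"{name} must be in [0, 1), got {cv}")
        if self.base_height <= 0:
            raise ValueError("base_height must be positive")
        if self.dna_quantity <= 0:
            raise ValueError("dna_quantity must be positive")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f.gene for f in self.freqs)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal factors with mean exactly 1 and given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _truth_frame(
    sample_ids: Sequence[str], gene: str, a1: np.ndarray, a2: np.ndarray
) -> pd.DataFrame:
    copies = np.array([ALLELE_COPIES[a] for a in a1]) + np.array(
        [ALLELE_COPIES[a] for a in a2]
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "gene": gene,
            "allele1": a1,
            "allele2": a2,
            "total_copies": copies,
        }
    )


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a cohort's true diplotypes under random mating.

    For each gene the two alleles of each individual are drawn i.i.d.
    from (p_del, p_wt, p_dup); genes are independent.  Returns a truth
    table with columns ``sample_id, gene, allele1, allele2,
    total_copies``, complete over samples x genes, reproducible for a
    fixed seed.
    """
    if not config.freqs:
        raise ValueError("SimConfig.freqs is empty: no genes to simulate")
    rng = np.random.default_rng(config.seed)
    ids = _sample_ids(config.n_samples)
    alleles = np.array(["del", "wt", "dup"])
    frames = []
    for spec in config.freqs:
        p = np.array([spec.p_del, spec.p_wt, spec.p_dup])
        draws = rng.choice(3, size=(config.n_samples, 2), p=p)
        frames.append(
            _truth_frame(ids, spec.gene, alleles[draws[:, 0]], alleles[draws[:, 1]])
        )
    return pd.concat(frames, ignore_index=True)


def _to_simplex(values: np.ndarray, what: str = "fractions") -> np.ndarray:
    """Validate fractions-or-percentages onto the simplex.

    Percentage input (sum near 100) is divided by 100.  A small drift of
    up to 0.002 in the total — the worst case for a published table of
    half-up-rounded percentages at one decimal — is renormalized away;
    anything larger is rejected as a genuine simplex violation.
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"{what} must be non-negative")
    total = vals.sum()
    if abs(total - 100.0) <= 0.2:  # percentage input with printed rounding
        vals = vals / total
    elif abs(total - 1.0) <= 0.002:
        vals = vals / total
    else:
        raise ValueError(f"{what} sum to {total:.6g}, expected 1 (or 100%)")
    return vals


def apportion(fractions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` among ``fractions``.

    Accepts fractions or percentages (see :func:`_to_simplex`).  The
    returned integer counts sum to ``n`` and each equals the floor or
    ceiling of its quota.
    """
    frac = _to_simplex(fractions)
    quota = frac * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_from_genotype_table(
    genotype_freqs: pd.DataFrame | Mapping[str, Mapping[str, float]],
    n: int,
    seed: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Draw a cohort's truth directly from diplotype-label frequencies.

    Parameters
    ----------
    genotype_freqs
        Label x gene table (rows are diplotype labels such as
        ``Del/Wt``, columns genes) of fractions or percentages.
    n
        Cohort size.
    seed
        Seed for the multinomial draw (ignored when ``exact``).
    exact
        When true, produce deterministic integer counts by
        largest-remainder apportionment instead of sampling, so the
        realized genotype frequencies reproduce the input table as
        closely as integers at ``n`` allow.
    """
    table = pd.DataFrame(genotype_freqs, dtype=float)
    unknown = set(table.index) - set(GENOTYPE_TO_ALLELES)
    if unknown:
        raise ValueError(f"unknown diplotype label(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    ids = _sample_ids(n)
    frames = []
    for gene in table.columns:
        col = table[gene].to_numpy()
        if exact:
            counts = apportion(col, n)
        else:
            try:
                frac = _to_simplex(col, what=f"{gene} genotype fractions")
            except ValueError:
                raise
            counts = rng.multinomial(n, frac)
        labels = np.repeat(table.index.to_numpy(), counts)
        if not exact:
            rng.shuffle(labels)
        a1 = np.array([GENOTYPE_TO_ALLELES[l][0] for l in labels])
        a2 = np.array([GENOTYPE_TO_ALLELES[l][1] for l in labels])
        frames.append(_truth_frame(ids, gene, a1, a2))
    return pd.concat(frames, ignore_index=True)


def reference_truth(genes: Sequence[str], n: int, prefix: str = "REF") -> pd.DataFrame:
    """Truth table of ``n`` wild-type (2-copy everywhere) reference samples."""
    ids = _sample_ids(n, prefix=prefix)
    frames = [
        _truth_frame(ids, gene, np.full(n, "wt"), np.full(n, "wt")) for gene in genes
    ]
    return pd.concat(frames, ignore_index=True)


def peaks_from_truth(
    truth: pd.DataFrame, panel: PanelDef, config: SimConfig
) -> pd.DataFrame:
    """Generate the MLPA peak table a truth table would produce.

    Requires the truth table to cover every panel gene for every sample.
    Returns a long DataFrame ``sample_id, probe_id, peak_height``
    covering all panel probes (targets, references, control fragments).
    """
    panel_genes = set(panel.genes)
    missing = panel_genes - set(truth["gene"])
    if missing:
        raise ValueError(f"truth table missing panel gene(s): {sorted(missing)}")
    copies = truth.pivot(index="sample_id", columns="gene", values="total_copies")
    if copies.isna().any().any():
        raise ValueError("truth table is not complete over samples x genes")
    sample_ids = copies.index.to_numpy()
    n = len(sample_ids)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scale = _lognormal_factors(rng, config.sample_scale_cv, n)
    is_male = rng.random(n) >= config.female_fraction

    base = config.base_height
    records: list[pd.DataFrame] = []

    def emit(probe_id: str, level: np.ndarray | float) -> None:
        noise = _lognormal_factors(rng, config.noise_cv, n)
        records.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "probe_id": probe_id,
                    "peak_height": base * level * scale * noise,
                }
            )
        )

    for probe in panel.probes:
        if probe.kind == "target":
            emit(probe.probe_id, copies[probe.gene].to_numpy(dtype=float) / 2.0)
        elif probe.kind == "reference":
            emit(probe.probe_id, 1.0)
        elif probe.kind == "q_fragment":
            emit(probe.probe_id, config.q_level / config.dna_quantity)
        elif probe.kind == "d_fragment":
            emit(probe.probe_id, 1.0)
        elif probe.kind == "x_fragment":
            emit(probe.probe_id, 1.0)
        elif probe.kind == "y_fragment":
            emit(probe.probe_id, np.where(is_male, 1.0, 0.0))
    out = pd.concat(records, ignore_index=True)
    # restore sample-major ordering for readable output
    out = out.sort_values(["sample_id", "probe_id"], kind="stable").reset_index(
        drop=True
    )
    return out


def simulate_run(
    config: SimConfig, panel: PanelDef, n_reference: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a full MLPA batch: cohort + wild-type reference samples.

    Returns ``(truth, peaks, reference_sample_ids)`` where ``truth``
    covers the test cohort only and ``peaks`` covers cohort plus
    reference samples.
    """
    truth = simulate_cohort(config)
    ref = reference_truth(config.genes, n_reference)
    peaks = peaks_from_truth(
        pd.concat([truth, ref], ignore_index=True), panel, config
    )
    return truth, peaks, sorted(ref["sample_id"].unique())


def calls_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Convert a truth table into a calls-shaped table of true genotypes.

    Useful for summarizing a cohort whose genotypes are known directly
    (e.g. drawn from a published genotype-frequency table) without
    passing through signal simulation.  The Del/Dup diplotype keeps its
    own label here; dosage-based calling can never produce it.
    """
    label_by_class = {
        "Del/Del": "HOM_DEL",
        "Del/Wt": "HET_DEL",
        "Wt/Wt": "NORMAL",
        "Dup/Wt": "HET_DUP",
        "Dup/Dup": "HOM_DUP",
        "Del/Dup": "AMBIGUOUS",
    }
    labels = [
        diplotype_label(a1, a2)
        for a1, a2 in zip(truth["allele1"], truth["allele2"])
    ]
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "gene": truth["gene"],
            "cnv_class": [label_by_class[l] for l in labels],
            "genotype_label": labels,
            "discordant": False,
            "n_probes_called": 0,
        }
    )
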