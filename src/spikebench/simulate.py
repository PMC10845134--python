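"""Synthetic DIA-NN-style benchmark matrices with known ground truth.

The generator emulates the canonical three-species A-vs-B design: human
background (expected log2FC 0), yeast spiked +1 and E. coli spiked -2,
measured in triplicate.  Per-entry base intensities are drawn
log-uniformly over a realistic dynamic range; replicate values get
multiplicative log-normal noise whose sigma is calibrated analytically
to the target CV; missingness is applied at random (optionally
intensity-dependent); contaminant rows, fold-change compression and a
global normalization shift on condition B can be injected to exercise
the error-detection paths of the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import QuantMatrix, RunDesign

__all__ = ["SimulationSpec", "simulate_benchmark", "write_diann_like", "make_run_design"]

DEFAULT_TRUE_LOG2FC = {"human": 0.0, "yeast": 1.0, "ecoli": -2.0}
# Entry counts roughly in the proportions of the 65:30:5 design's
# identifiable proteomes (human >> yeast > E. coli).
DEFAULT_N_ENTRIES = {"human": 1000, "yeast": 500, "ecoli": 300}

_SUFFIX = {"human": "HUMAN", "yeast": "YEAST", "ecoli": "ECOLI"}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic benchmark data set.

    ``cv_target`` is the expected per-entry CV in percent;
    ``compression_factor`` scales the true log2 fold changes (1 =
    faithful, <1 = ratio compression, >1 = expansion); the scaling is
    heterogeneous across entries with this value as the mean, because
    real distortion hits entries unevenly and that heterogeneity is what
    skews the fold-change density; ``shift_b`` is a global
    normalization-error injection that offsets every A/B log2 ratio by
    +shift_b (condition B is scaled down accordingly, applied last);
    ``outlier_fraction`` moves
    that fraction of entries' fold changes by ``outlier_shift`` log2
    units, mimicking a shifted subpopulation.  The seed fully determines
    the output.
    """

    n_entries: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_ENTRIES))
    true_log2fc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_LOG2FC))
    log10_intensity_range: tuple[float, float] = (4.0, 8.0)
    cv_target: float = 10.0
    missing_rate: float = 0.05
    n_replicates: int = 3
    compression_factor: float = 1.0
    contaminant_count: int = 20
    shift_b: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    intensity_dependent_missing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_target <= 0:
            raise ValueError("cv_target must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.compression_factor < 0:
            raise ValueError("compression_factor must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per condition")
        if set(self.n_entries) != set(self.true_log2fc):
            raise ValueError("n_entries and true_log2fc must cover the same species")
        if any(n < 0 for n in self.n_entries.values()):
            raise ValueError("entry counts must be non-negative")


def make_run_design(n_replicates: int = 3) -> RunDesign:
    """The matching A-vs-B run design (A_r1..A_rn, B_r1..B_rn)."""
    runs = [f"A_r{i+1}" for i in range(n_replicates)] + [
        f"B_r{i+1}" for i in range(n_replicates)
    ]
    conds = ["A"] * n_replicates + ["B"] * n_replicates
    reps = list(range(1, n_replicates + 1)) * 2
    return RunDesign(tuple(runs), tuple(conds), tuple(reps))


def simulate_benchmark(spec: SimulationSpec) -> tuple[QuantMatrix, pd.DataFrame]:
    """Generate a quantification matrix plus its ground-truth table.

    Per entry, a base intensity B is drawn log10-uniformly; the
    condition means are B * 2^(+c*fc/2) and B * 2^(-c*fc/2) where c is
    the compression factor and fc the species' true log2 fold change.
    Replicates are mean-preserving log-normal draws with
    sigma = sqrt(ln(1 + (CV/100)^2)), so the expected CV equals
    ``cv_target`` exactly.  Contaminant rows (``CON__``) behave like
    background (fc 0).  The truth table records species, the true
    (uncompressed and applied) fold changes and all spec parameters.
    """
    rng = np.random.default_rng(spec.seed)
    design = make_run_design(spec.n_replicates)
    n_a = spec.n_replicates

    ids: list[str] = []
    species_labels: list[str] = []
    true_fc: list[float] = []
    for sp in sorted(spec.n_entries):
        n = spec.n_entries[sp]
        ids.extend(f"P{i:05d}_{_SUFFIX.get(sp, sp.upper())}" for i in range(n))
        species_labels.extend([sp] * n)
        true_fc.extend([spec.true_log2fc[sp]] * n)
    for i in range(spec.contaminant_count):
        ids.append(f"CON__Q{i:05d}")
        species_labels.append("contaminant")
        true_fc.append(0.0)

    n_entries = len(ids)
    true_fc_arr = np.asarray(true_fc)
    c = spec.compression_factor
    if c == 1.0:
        applied_fc = true_fc_arr.copy()
    else:
        # Ratio distortion is heterogeneous across entries (interference
        # hits entries unevenly), so the injected multiplier varies per
        # entry with mean exactly c.  Compression (c < 1) draws c_i from
        # a rising-quadratic density on [4c-3, 1]: the mode stays at 1
        # (unaffected entries) with a tail toward strong attenuation,
        # which skews the fold-change density toward zero (oriented
        # AF < 1) as in real compressed data.  Below c = 0.75 the tail
        # crosses zero — severe interference can invert apparent ratios,
        # which is what also drives classification errors up.  Expansion
        # (c > 1) mirrors this with a tail toward larger fold changes.
        u = rng.random(n_entries)
        if c < 1.0:
            lo = 4.0 * c - 3.0
            c_i = lo + (1.0 - lo) * u ** (1.0 / 3.0)
        else:
            hi = 4.0 * c - 3.0
            c_i = hi - (hi - 1.0) * u ** (1.0 / 3.0)
        applied_fc = c_i * true_fc_arr
    if spec.outlier_fraction > 0:
        outlier = rng.random(n_entries) < spec.outlier_fraction
        applied_fc = applied_fc + np.where(outlier, spec.outlier_shift, 0.0)
    else:
        outlier = np.zeros(n_entries, dtype=bool)

    lo, hi = spec.log10_intensity_range
    base = 10.0 ** rng.uniform(lo, hi, size=n_entries)
    mean_a = base * 2.0 ** (applied_fc / 2.0)
    mean_b = base * 2.0 ** (-applied_fc / 2.0)

    sigma = math.sqrt(math.log1p((spec.cv_target / 100.0) ** 2))
    mu_correction = -0.5 * sigma**2  # mean-preserving log-normal

    def draw(means: np.ndarray) -> np.ndarray:
        z = rng.standard_normal((n_entries, n_a))
        return means[:, None] * np.exp(sigma * z + mu_correction)

    values = np.hstack([draw(mean_a), draw(mean_b)])

    if spec.missing_rate > 0:
        if spec.intensity_dependent_missing:
            # logistic in log10 intensity: low-abundance entries drop out more
            logi = np.log10(values)
            mid = np.quantile(logi, spec.missing_rate)
            p_miss = 1.0 / (1.0 + np.exp(2.0 * (logi - mid)))
            p_miss *= spec.missing_rate / max(p_miss.mean(), 1e-12)
            mask = rng.random(values.shape) < np.clip(p_miss, 0, 0.95)
        else:
            mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    # shift_b is the log2 offset the error adds to every A/B ratio, so
    # condition B is scaled down by 2^shift_b
    if spec.shift_b != 0.0:
        values[:, n_a:] *= 2.0 ** (-spec.shift_b)

    inten = pd.DataFrame(values, index=pd.Index(ids, name="Protein.Group"),
                         columns=list(design.run_ids))
    matrix = QuantMatrix(
        inten,
        level="protein_group",
        species=pd.Series(
            [sp if sp != "contaminant" else "unknown" for sp in species_labels],
            index=inten.index,
        ),
        is_contaminant=pd.Series(
            [s.startswith("CON__") for s in ids], index=inten.index
        ),
    )
    truth = pd.DataFrame(
        {
            "species": species_labels,
            "true_log2fc": true_fc_arr,
            "applied_log2fc": applied_fc,
            "is_outlier": outlier,
        },
        index=inten.index,
    )
    truth.attrs["spec"] = asdict(spec)
    return matrix, truth


def write_diann_like(matrix: QuantMatrix, path) -> None:
    """Write the matrix as a DIA-NN-style wide TSV (round-trips through
    :func:`spikebench.io.read_quant_matrix`; missing cells are empty)."""
    out = matrix.intensities.copy()
    out.insert(0, "species", matrix.species)
    out.to_csv(path, sep="\t", index=True, float_format="%.17g", na_rep="")
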