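"""Synthetic DMH datasets with known ground truth.

The generator builds a synthetic chromosome and probe annotation in
which internal control probes sit in planted recognition-site-free
900+ base windows while every other probe has at least one CCGG site in
its window, then simulates two-color intensities with the statistical
structure the preprocessing methods assume:

* per channel, foreground = S + B with S ~ Exponential(mean alpha) and
  B ~ Normal(mu, sigma^2) — the normexp convolution; the background
  column is drawn separately (truncated normal);
* red and green true signals are coupled through a Gaussian copula, so
  both marginals stay exponential while the log-ratio M carries probe-
  and array-level noise;
* CpG islands designated methylated multiply the red-channel signal by
  2^delta on their methylation-positive arrays;
* a smooth intensity-dependent dye-bias curve c(A) is applied in log
  space, half to each channel, so A is approximately preserved;
* control probes receive no differential effect: their expected M is 0
  before dye bias.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import GenerationError
from .io import (
    DEFAULT_DIALECT,
    GenomeSequences,
    ProbeAnnotation,
    TwoColorArray,
    write_genome_fasta,
    write_probe_annotation,
)
from .restriction import DEFAULT_MOTIFS, DEFAULT_WINDOW, find_recognition_sites


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults for the simulated datasets.

    Array counts and control-gene group sizes mirror the DMH study
    design this package targets (26 or 40 arrays, 30-32 methylated
    genes, 47 housekeeping genes, 199 internal control probes); the
    intensity model parameters are desk-scale choices documented in
    docs/methods.md.
    """

    n_arrays: int = 26
    n_methylated_islands: int = 32
    n_housekeeping_islands: int = 47
    n_other_islands: int = 40
    probes_per_island: int = 6
    n_control_probes: int = 199
    probe_length: int = 60
    spacing: int = 1000
    window: int = DEFAULT_WINDOW
    # methylation signal
    delta: float = 1.0
    prevalence: float = 0.7
    # intensity model (arbitrary fluorescence units)
    alpha: float = 1000.0
    mu: float = 100.0
    sigma: float = 50.0
    bg_mu: float = 50.0
    bg_sigma: float = 10.0
    rho: float = 0.95
    dye_affinity_sd: float = 0.08
    # dye bias polynomial c(A) = c0 + c1 (A - a_ref) + c2 (A - a_ref)^2
    dye_bias_coeffs: tuple = (0.4, -0.1, 0.02)
    dye_bias_ref: float = 10.0

    @property
    def n_islands(self) -> int:
        return self.n_methylated_islands + self.n_housekeeping_islands + self.n_other_islands


PRESETS = {
    "ovarian": SyntheticConfig(n_arrays=26, n_methylated_islands=32),
    "breast": SyntheticConfig(n_arrays=40, n_methylated_islands=30),
}


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    seed: int
    control_probe_ids: frozenset
    island_ids: tuple
    housekeeping_island_ids: tuple
    methylated_island_ids: tuple = ()
    #: islands x arrays boolean indicator of hypermethylation
    methylation_indicators: pd.DataFrame | None = None
    delta: float = 0.0
    dye_bias_coeffs: tuple = (0.0,)
    dye_bias_ref: float = 10.0
    normexp_truth: dict | None = None


def dye_bias_curve(A, coeffs: Sequence[float], ref: float):
    """Evaluate the dye-bias polynomial c(A) at the given A values."""
    x = np.asarray(A, dtype=float) - ref
    out = np.zeros_like(x)
    for power, c in enumerate(coeffs):
        out += c * x**power
    return out


def _scrub_motifs(seq: bytearray, lo: int, hi: int, motifs) -> None:
    """Mutate bases until [lo, hi) contains no recognition motif.

    The third motif base is replaced by 'A'; A occurs in neither default
    motif, so no replacement can create a new occurrence.
    """
    while True:
        text = seq[lo:hi].decode()
        sites = find_recognition_sites(text, motifs)
        if not sites:
            return
        for site in sites:
            seq[lo + site.offset + 2] = ord("A")


def generate_layout(
    n_islands: int,
    probes_per_island: int,
    n_control_probes: int,
    n_housekeeping_islands: int,
    seed: int,
    probe_length: int = 60,
    spacing: int = 1000,
    window: int = DEFAULT_WINDOW,
    motifs=DEFAULT_MOTIFS,
) -> tuple[GenomeSequences, ProbeAnnotation, SyntheticTruth]:
    """Build the synthetic chromosome, probe annotation and truth skeleton.

    Control probes are planted in recognition-site-free ``window``-base
    regions; every island probe gets at least one CCGG site inside its
    window.  Islands receive ``probes_per_island`` consecutive probes,
    the first of which is promoter-flagged.  Island and control units
    are interleaved in random order along the chromosome.
    """
    for name, v in (
        ("n_islands", n_islands),
        ("probes_per_island", probes_per_island),
        ("n_control_probes", n_control_probes),
        ("n_housekeeping_islands", n_housekeeping_islands),
    ):
        if v <= 0:
            raise GenerationError(f"{name} must be > 0, got {v}")
    if n_housekeeping_islands >= n_islands:
        raise GenerationError(
            f"need n_islands ({n_islands}) > n_housekeeping_islands ({n_housekeeping_islands})"
        )
    if probes_per_island < 3:
        raise GenerationError("islands need >= 3 probes to be scoreable")
    if spacing < window + probe_length:
        raise GenerationError(
            f"spacing {spacing} too small for window {window}: probe windows would overlap"
        )
    rng = np.random.default_rng(seed)
    n_probes = n_islands * probes_per_island + n_control_probes
    margin = window
    length = n_probes * spacing + 2 * margin
    if length > 50_000_000:
        raise GenerationError(f"requested layout needs a {length} bp chromosome; too large")
    seq = bytearray(rng.choice([ord(c) for c in "ACGT"], size=length).astype(np.uint8).tobytes())

    # interleave island units (probes_per_island slots) and control units
    units = [("island", i) for i in range(n_islands)] + [("control", i) for i in range(n_control_probes)]
    order = rng.permutation(len(units))
    hk = rng.choice(n_islands, size=n_housekeeping_islands, replace=False)
    hk_set = set(int(i) for i in hk)
    island_ids = []
    rows = []
    half_window = window // 2
    slot = 0
    for idx in order:
        kind, i = units[idx]
        if kind == "control":
            center = margin + slot * spacing
            probe_id = f"ctl_{i + 1:04d}"
            _scrub_motifs(seq, center - half_window, center + half_window, motifs)
            rows.append((probe_id, center, None, False))
            slot += 1
        else:
            island_id = f"hk_{i + 1:04d}" if i in hk_set else f"cgi_{i + 1:04d}"
            island_ids.append(island_id)
            for p in range(probes_per_island):
                center = margin + slot * spacing
                probe_id = f"{island_id}_p{p + 1}"
                pos = center + 20
                seq[pos : pos + 4] = b"CCGG"
                rows.append((probe_id, center, island_id, p == 0))
                slot += 1

    ann_rows = []
    half_probe = probe_length // 2
    for probe_id, center, island_id, promoter in rows:
        ann_rows.append(
            {
                "probe_id": probe_id,
                "chrom": "chrS",
                "start": center - half_probe,
                "end": center + (probe_length - half_probe),
                "island_id": island_id,
                "in_promoter": promoter,
            }
        )
    annotation = ProbeAnnotation(pd.DataFrame(ann_rows))
    genome = GenomeSequences()
    genome["chrS"] = seq.decode()
    truth = SyntheticTruth(
        seed=seed,
        control_probe_ids=frozenset(r[0] for r in rows if r[2] is None),
        island_ids=tuple(island_ids),
        housekeeping_island_ids=tuple(i for i in island_ids if i.startswith("hk_")),
    )
    return genome, annotation, truth


def simulate_dataset(
    annotation: ProbeAnnotation,
    truth: SyntheticTruth,
    n_arrays: int,
    seed: int,
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[TwoColorArray], SyntheticTruth]:
    """Simulate two-color intensities over a layout; completes the truth.

    ``config`` supplies the intensity model; ``truth`` must come from
    :func:`generate_layout` on the same annotation.  Methylated islands
    are drawn from the non-housekeeping islands
    (``config.n_methylated_islands`` of them) and are hypermethylated on
    a Bernoulli(``config.prevalence``) subset of arrays (at least one).
    """
    if n_arrays < 2:
        raise GenerationError(f"n_arrays must be >= 2, got {n_arrays}")
    if config.delta < 0:
        raise GenerationError(f"delta must be >= 0, got {config.delta}")
    if not 0 < config.prevalence <= 1:
        raise GenerationError(f"prevalence must be in (0, 1], got {config.prevalence}")
    rng = np.random.default_rng(seed)
    d = annotation.data
    n_probes = len(d)
    probe_ids = d["probe_id"].to_numpy()
    island_of = d["island_id"].to_numpy(dtype=object)

    candidates = [i for i in truth.island_ids if i not in truth.housekeeping_island_ids]
    if config.n_methylated_islands > len(candidates):
        raise GenerationError(
            f"cannot pick {config.n_methylated_islands} methylated islands from {len(candidates)} candidates"
        )
    methylated = tuple(
        sorted(rng.choice(candidates, size=config.n_methylated_islands, replace=False))
    )
    indicators = pd.DataFrame(
        False,
        index=list(methylated),
        columns=[f"array_{a + 1:02d}" for a in range(n_arrays)],
    )
    for island in methylated:
        row = rng.random(n_arrays) < config.prevalence
        while not row.any():
            row = rng.random(n_arrays) < config.prevalence
        indicators.loc[island] = row

    # per-probe dye affinity (log2 units); controls stay at exactly zero
    is_control = np.fromiter((p in truth.control_probe_ids for p in probe_ids), bool, n_probes)
    dye_affinity = rng.normal(0.0, config.dye_affinity_sd, n_probes)
    dye_affinity[is_control] = 0.0

    meth_effect = np.zeros((n_probes, n_arrays))
    for j, island in enumerate(island_of):
        if island in indicators.index:
            meth_effect[j] = indicators.loc[island].to_numpy() * config.delta

    eps = 1e-12
    arrays = []
    for a in range(n_arrays):
        z1 = rng.standard_normal(n_probes)
        z2 = rng.standard_normal(n_probes)
        z_g = z1
        z_r = config.rho * z1 + np.sqrt(1.0 - config.rho**2) * z2
        u_g = np.clip(special.ndtr(z_g), eps, 1 - eps)
        u_r = np.clip(special.ndtr(z_r), eps, 1 - eps)
        s_g = -config.alpha * np.log1p(-u_g)
        s_r = -config.alpha * np.log1p(-u_r)
        lr = np.log2(s_r) + meth_effect[:, a] + dye_affinity / 2.0
        lg = np.log2(s_g) - dye_affinity / 2.0
        s_r, s_g = np.exp2(lr), np.exp2(lg)

        def _noisy(signal):
            out = signal + rng.normal(config.mu, config.sigma, n_probes)
            bad = out < 0
            while bad.any():
                out[bad] = signal[bad] + rng.normal(config.mu, config.sigma, bad.sum())
                bad = out < 0
            return out

        def _background():
            out = rng.normal(config.bg_mu, config.bg_sigma, n_probes)
            bad = out < 0
            while bad.any():
                out[bad] = rng.normal(config.bg_mu, config.bg_sigma, bad.sum())
                bad = out < 0
            return out

        rf, gf = _noisy(s_r), _noisy(s_g)
        # dye bias acts on the measured fluorescence: symmetric in log
        # space as a smooth function of the measured average intensity,
        # so A is preserved exactly while M picks up the bias curve
        a_meas = 0.5 * (np.log2(rf) + np.log2(gf))
        bias = dye_bias_curve(a_meas, truth.dye_bias_coeffs, truth.dye_bias_ref)
        rf = rf * np.exp2(bias / 2.0)
        gf = gf * np.exp2(-bias / 2.0)
        arrays.append(
            TwoColorArray(
                array_id=f"array_{a + 1:02d}",
                data=pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "Rf": rf,
                        "Gf": gf,
                        "Rb": _background(),
                        "Gb": _background(),
                    }
                ),
            )
        )

    completed = dataclasses.replace(
        truth,
        methylated_island_ids=methylated,
        methylation_indicators=indicators,
        delta=config.delta,
        normexp_truth={
            "R": {"alpha": config.alpha, "mu": config.mu - config.bg_mu,
                  "sigma": float(np.hypot(config.sigma, config.bg_sigma))},
            "G": {"alpha": config.alpha, "mu": config.mu - config.bg_mu,
                  "sigma": float(np.hypot(config.sigma, config.bg_sigma))},
        },
    )
    return arrays, completed


def generate_dataset(
    config: SyntheticConfig = SyntheticConfig(), seed: int = 0
):
    """Layout + simulation in one call.

    Returns (genome, annotation, arrays, truth).  The truth's dye-bias
    coefficients are taken from ``config``.
    """
    genome, annotation, truth = generate_layout(
        n_islands=config.n_islands,
        probes_per_island=config.probes_per_island,
        n_control_probes=config.n_control_probes,
        n_housekeeping_islands=config.n_housekeeping_islands,
        seed=seed,
        probe_length=config.probe_length,
        spacing=config.spacing,
        window=config.window,
    )
    truth = dataclasses.replace(
        truth, dye_bias_coeffs=tuple(config.dye_bias_coeffs), dye_bias_ref=config.dye_bias_ref
    )
    arrays, truth = simulate_dataset(annotation, truth, config.n_arrays, seed + 1, config)
    return genome, annotation, arrays, truth


def m_noise_sample(n: int, seed: int, config: SyntheticConfig = SyntheticConfig()) -> np.ndarray:
    """Draws from the null M-noise distribution of the intensity model.

    Simulates background-subtracted two-channel intensities for
    unmethylated, bias-free probes and returns log2(R/G) for the draws
    where both channels are positive (matching the missingness rule of
    the M computation).
    """
    rng = np.random.default_rng(seed)
    eps = 1e-12
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    u_g = np.clip(special.ndtr(z1), eps, 1 - eps)
    u_r = np.clip(special.ndtr(config.rho * z1 + np.sqrt(1 - config.rho**2) * z2), eps, 1 - eps)
    s_g = -config.alpha * np.log1p(-u_g)
    s_r = -config.alpha * np.log1p(-u_r)
    R = s_r + rng.normal(config.mu, config.sigma, n) - rng.normal(config.bg_mu, config.bg_sigma, n)
    G = s_g + rng.normal(config.mu, config.sigma, n) - rng.normal(config.bg_mu, config.bg_sigma, n)
    ok = (R > 0) & (G > 0)
    return np.log2(R[ok] / G[ok])


def simulate_null_island_blocks(
    n_islands: int,
    n_probes: int,
    n_arrays: int,
    seed: int,
    config: SyntheticConfig = SyntheticConfig(),
    probe_sd: float = 0.2,
    pool_size: int = 1_000_000,
) -> list[pd.DataFrame]:
    """Island M blocks satisfying the scoring model's null exactly.

    Each block is probes x arrays with M_ap = probe_p + e_ap, probe
    effects centred normal with sd ``probe_sd``, and errors drawn iid
    from the generator's M-noise distribution recentred so its 75th
    percentile is zero — i.e. the island quantile model holds with every
    array coefficient equal to zero.  (Raw delta = 0 simulator output is
    *not* such a null: its noise is symmetric about zero, so its 75th
    percentile — the quantity the one-sided test targets — is positive.)
    """
    pool = m_noise_sample(pool_size, seed, config)
    pool = pool - np.quantile(pool, 0.75)
    rng = np.random.default_rng(seed + 1)
    blocks = []
    cols = [f"array_{a + 1:02d}" for a in range(n_arrays)]
    for i in range(n_islands):
        probe = rng.normal(0.0, probe_sd, n_probes)
        probe -= probe.mean()
        e = rng.choice(pool, size=(n_probes, n_arrays))
        blocks.append(
            pd.DataFrame(
                probe[:, None] + e,
                index=[f"null_{i:04d}_p{j + 1}" for j in range(n_probes)],
                columns=cols,
            )
        )
    return blocks


def write_dataset(genome, annotation, arrays, truth, outdir) -> None:
    """Write FASTA + BED + per-array feature TSVs + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(genome, outdir / "genome.fa")
    write_probe_annotation(annotation, outdir / "probes.bed")
    for arr in arrays:
        out = pd.DataFrame({DEFAULT_DIALECT[field]: arr.data[field] for field in
                            ("probe_id", "Rf", "Gf", "Rb", "Gb")})
        out.to_csv(outdir / f"{arr.array_id}.tsv", sep="\t", index=False, float_format="%.4f")
    payload = {
        "seed": truth.seed,
        "delta": truth.delta,
        "control_probe_ids": sorted(truth.control_probe_ids),
        "island_ids": list(truth.island_ids),
        "housekeeping_island_ids": list(truth.housekeeping_island_ids),
        "methylated_island_ids": list(truth.methylated_island_ids),
        "methylation_indicators": {
            island: [c for c in truth.methylation_indicators.columns
                     if bool(truth.methylation_indicators.loc[island, c])]
            for island in truth.methylation_indicators.index
        }
        if truth.methylation_indicators is not None
        else {},
        "dye_bias_coeffs": list(truth.dye_bias_coeffs),
        "dye_bias_ref": truth.dye_bias_ref,
        "normexp_truth": truth.normexp_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
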