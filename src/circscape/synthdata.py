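"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the landscape pipeline gets a testable,
download-free input surface here:

* ``gen_junction_counts`` — negative-binomial BSJ and linear junction
  counts for a differentiation series (5 states x 3 replicates by
  default, mirroring a stem-cell-to-progenitor design) in which a chosen
  fraction of circRNAs rises monotonically across states while linear
  host counts either track the circle (host-coupled) or stay flat;
* ``gen_transcriptome`` — uniform-random transcripts with an optional
  planted guide target site for off-target scanner round trips;
* ``gen_cluster_table`` — cluster x condition cell tables with planted
  condition-specific clusters;
* ``gen_depth_profile`` — 1-D cortical depth profiles with planted
  UL/DL/VZ mass fractions.

All generators take an explicit seed and draw from one local
``numpy.random.Generator`` — identical parameters and seed give
bit-identical output. Each returns a ``SyntheticTruth`` recording the
planted structure so recovery tests can compare calls against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circquant import CircCandidate, JunctionCountSet

__all__ = [
    "LandscapeParams",
    "SyntheticTruth",
    "gen_junction_counts",
    "gen_transcriptome",
    "gen_cluster_table",
    "gen_depth_profile",
]

CONDITION_NAMES = ("hESC", "NEP", "rNPC", "NMP", "cNPC")


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the differentiation-landscape count generator.

    Defaults are the study-scale conditions: 417 high-abundance
    candidates over 5 cell states x 3 replicates, a 1.0 mean log2
    fold-change per state step for the upregulated majority, and
    8-12 M total reads per sample.
    """

    n_circ: int = 417
    n_conditions: int = 5
    n_reps: int = 3
    frac_up: float = 0.7
    frac_host_coupled: float = 0.3
    base_mu: float = 8.0
    effect_log2fc: float = 1.0
    dispersion: float = 0.3
    libsize_range: tuple[float, float] = (8e6, 12e6)
    linear_ratio: float = 5.0       # linear host reads per BSJ read, state 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_up <= 1:
            raise ValueError("frac_up must lie in [0, 1]")
        if not 0 <= self.frac_host_coupled <= 1:
            raise ValueError("frac_host_coupled must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.libsize_range[0] > self.libsize_range[1]:
            raise ValueError("libsize_range min must be <= max")
        if self.libsize_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        if self.base_mu <= 0:
            raise ValueError("base_mu must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests. Only the fields relevant
    to the generator that produced it are populated."""

    regulation: list[str] = field(default_factory=list)       # up/down/flat
    host_coupled: list[bool] = field(default_factory=list)
    state_means: np.ndarray | None = None                     # n_circ x states
    planted_site: dict | None = None                          # transcriptome
    biased_clusters: dict[str, str] = field(default_factory=dict)
    subregion_fractions: dict[str, float] | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mean, dispersion) with var = mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_junction_counts(
    params: LandscapeParams,
) -> tuple[JunctionCountSet, SyntheticTruth]:
    """Generate BSJ + linear junction count matrices for the landscape.

    Per-candidate baseline means are lognormal around ``base_mu``; the
    first ``frac_up`` fraction of candidates (in a seed-shuffled order)
    gains ``effect_log2fc`` log2 units per state step, the rest stay
    flat. Host-coupled candidates' linear means track their circ means;
    independent candidates keep state-1 linear means throughout. Expected
    counts scale with each sample's library size (relative to the mean
    library size), so RPM is exercised by construction.
    """
    rng = np.random.default_rng(params.seed)
    n, k, r = params.n_circ, params.n_conditions, params.n_reps

    # candidate loci: distinct synthetic coordinates, strand alternating
    candidates = [
        CircCandidate(
            chrom=f"chr{1 + i % 22}",
            start=10_000 + 50_000 * i,
            end=10_000 + 50_000 * i + int(rng.integers(500, 20_000)),
            strand="+" if i % 2 == 0 else "-",
            annotation_id=f"synth_circ_{i:07d}",
            callers=frozenset({"find_circ"}),
        )
        for i in range(n)
    ]
    ids = [c.id for c in candidates]

    n_up = int(round(params.frac_up * n))
    order = rng.permutation(n)
    regulation = np.array(["flat"] * n, dtype=object)
    regulation[order[:n_up]] = "up"
    if params.effect_log2fc == 0:
        regulation[:] = "flat"
        n_up = 0
    n_coupled = int(round(params.frac_host_coupled * n))
    coupled = np.zeros(n, dtype=bool)
    coupled[rng.permutation(n)[:n_coupled]] = True

    base = params.base_mu * rng.lognormal(mean=0.0, sigma=0.8, size=n)
    steps = np.arange(k)
    up_mask = (regulation == "up").astype(float)
    log2_gain = np.outer(up_mask * params.effect_log2fc, steps)
    state_means = base[:, None] * (2.0 ** log2_gain)          # n x k

    linear_base = base * params.linear_ratio
    linear_means = np.where(
        coupled[:, None],
        state_means * params.linear_ratio,
        np.repeat(linear_base[:, None], k, axis=1),
    )

    conds = [
        CONDITION_NAMES[j] if k <= len(CONDITION_NAMES) else f"state{j + 1}"
        for j in range(k)
    ]
    sample_ids, sample_cond, sample_rep = [], [], []
    for j, cond in enumerate(conds):
        for rep in range(1, r + 1):
            sample_ids.append(f"{cond}_rep{rep}")
            sample_cond.append(cond)
            sample_rep.append(rep)
    m = k * r
    libsizes = rng.uniform(*params.libsize_range, size=m)
    scale = libsizes / libsizes.mean()

    mu_bsj = np.repeat(state_means, r, axis=1) * scale[None, :]
    mu_lin = np.repeat(linear_means, r, axis=1) * scale[None, :]
    bsj = _nb_draw(rng, mu_bsj, params.dispersion)
    donor = _nb_draw(rng, mu_lin, params.dispersion)
    acceptor = _nb_draw(rng, mu_lin, params.dispersion)

    samples = pd.DataFrame(
        {
            "condition": sample_cond,
            "replicate": sample_rep,
            "library_size": libsizes,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    jcs = JunctionCountSet(
        candidates=candidates,
        samples=samples,
        bsj=pd.DataFrame(bsj, index=ids, columns=sample_ids),
        donor_linear=pd.DataFrame(donor, index=ids, columns=sample_ids),
        acceptor_linear=pd.DataFrame(acceptor, index=ids, columns=sample_ids),
    )
    truth = SyntheticTruth(
        regulation=list(regulation),
        host_coupled=list(coupled),
        state_means=state_means,
    )
    return jcs, truth


def gen_transcriptome(
    n_transcripts: int,
    length: int,
    planted_guide: str | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Uniform-random ACGT transcripts, optionally with one planted guide
    target site (the reverse complement of the guide) at a recorded
    position in the first transcript."""
    rng = np.random.default_rng(seed)
    if planted_guide is not None:
        g = planted_guide.upper().replace("U", "T")
        if not g or any(ch not in "ACGT" for ch in g):
            raise ValueError(f"guide must be ACGT/ACGU, got {planted_guide!r}")
        if len(g) > length:
            raise ValueError("planted guide longer than transcripts")
    alphabet = np.array(list("ACGT"))
    records = [
        (f"NM_{i + 1:06d}", "".join(rng.choice(alphabet, size=length)))
        for i in range(n_transcripts)
    ]
    truth = SyntheticTruth()
    if planted_guide is not None and n_transcripts > 0:
        comp = str.maketrans("ACGT", "TGCA")
        site = g.translate(comp)[::-1]
        pos = int(rng.integers(0, length - len(site) + 1))
        tid, seq = records[0]
        records[0] = (tid, seq[:pos] + site + seq[pos + len(site):])
        truth.planted_site = {
            "transcript_id": tid,
            "position": pos,
            "site": site,
            "guide": planted_guide,
        }
    return records, truth


def gen_cluster_table(
    n_clusters: int = 10,
    cells_per_cluster: int = 500,
    biased_clusters: int = 3,
    bias_level: float = 0.9,
    conditions: tuple[str, str] = ("CTRL", "KD"),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cell table with ``biased_clusters`` clusters drawn toward one
    condition with probability ``bias_level``; the rest are 50/50
    binomial. Returns a per-cell table usable by ``condition_bias`` plus
    the planted cluster -> condition truth."""
    if not 0.5 < bias_level <= 1:
        raise ValueError("bias_level must lie in (0.5, 1]")
    if biased_clusters > n_clusters:
        raise ValueError("more biased clusters than clusters")
    rng = np.random.default_rng(seed)
    biased_idx = rng.permutation(n_clusters)[:biased_clusters]
    assigned = {
        int(c): conditions[i % 2] for i, c in enumerate(sorted(biased_idx))
    }
    rows = []
    for c in range(n_clusters):
        name = f"cluster{c:02d}"
        if c in assigned:
            p_first = bias_level if assigned[c] == conditions[0] else 1 - bias_level
        else:
            p_first = 0.5
        draws = rng.random(cells_per_cluster) < p_first
        for j, is_first in enumerate(draws):
            rows.append(
                {
                    "cell_id": f"{name}_cell{j:04d}",
                    "cluster": name,
                    "condition": conditions[0] if is_first else conditions[1],
                    "umi_count": int(rng.integers(500, 5000)),
                    "pct_mito": float(rng.uniform(0, 5)),
                    "n_genes": int(rng.integers(200, 2500)),
                }
            )
    truth = SyntheticTruth(
        biased_clusters={f"cluster{c:02d}": cond for c, cond in assigned.items()}
    )
    return pd.DataFrame(rows), truth


def gen_depth_profile(
    n_points: int = 1000,
    ul_frac: float = 0.94,
    dl_frac: float = 0.05,
    vz_frac: float = 0.01,
    ctip2_interval: tuple[float, float] = (0.25, 0.55),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """1-D depth-intensity profile with planted UL/DL/VZ mass fractions.

    Positions are grid-cell midpoints on [0, 1]; within each subregion
    (VZ = [0, lo), DL = [lo, hi], UL = (hi, 1], matching the quantifier's
    conventions) the requested mass is spread uniformly, so a noiseless
    profile round-trips exactly. Gaussian noise (sd ``noise_sd``) is added
    and clipped at zero.
    """
    from .migration import DepthProfile

    total = ul_frac + dl_frac + vz_frac
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    lo, hi = ctip2_interval
    if not (0 <= lo < hi <= 1):
        raise ValueError("ctip2_interval must satisfy 0 <= lo < hi <= 1")
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_points) + 0.5) / n_points
    in_vz = pos < lo
    in_dl = (pos >= lo) & (pos <= hi)
    in_ul = pos > hi
    intensity = np.zeros(n_points)
    for mask, frac in ((in_vz, vz_frac), (in_dl, dl_frac), (in_ul, ul_frac)):
        if mask.sum() == 0 and frac > 0:
            raise ValueError("a subregion with mass contains no grid points")
        if mask.sum():
            intensity[mask] = frac / mask.sum()
    if noise_sd > 0:
        intensity = np.clip(intensity + rng.normal(0, noise_sd, n_points), 0, None)
    profile = DepthProfile(
        positions=pos, intensity=intensity, ctip2_interval=(lo, hi)
    )
    truth = SyntheticTruth(
        subregion_fractions={"UL": ul_frac, "DL": dl_frac, "VZ": vz_frac}
    )
    return profile, truth
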