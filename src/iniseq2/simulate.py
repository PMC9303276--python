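"""Density-substitution read simulator with ground truth.

Models the in-vitro labelling experiment: in each of ``n_nuclei`` nuclei,
every planted origin fires independently with probability equal to its
efficiency; a fired origin replicates a tract on each side of its centre
whose half-length is a deterministic core plus an exponential tail
(mean ``tract_mean * incubation_scale`` per side; the core is
``tract_core_fraction`` of the mean). The core reproduces the flat plateau
of complete LL depletion seen at efficient origins; the tail models
non-processive fork escape (``tract_core_fraction=0`` gives a purely
memoryless tract). The per-bp replicated fraction f(x) is the fraction of nuclei in
which x lies inside at least one fired tract. Read libraries are emitted by
per-bp Poisson sampling:

    HL rate(x) = depth * (f(x) * (1 - bg) + (1 - f(x)) * bg)
    LL rate(x) = depth * ((1 - f(x)) * (1 - bg) + f(x) * bg)

where ``bg`` models gradient cross-contamination. Expected HL + LL rate is
``depth`` everywhere (conservation before Poisson noise), and a fixed seed
gives bit-identical output.

A note on the default layout: the caller normalizes each library to
reads-per-million of its own total, so called efficiencies track planted
replicated fractions faithfully only when the replicated and unreplicated
DNA pools are of comparable size (see docs/methods.md). The default
configuration therefore plants origins densely enough that roughly half of
the toy genome replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeLayout, ReadSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedOrigin:
    chrom: str
    center: int
    efficiency: float
    tract_mean: float  # mean tract half-length in bp (per side, before scaling)

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")
        if self.tract_mean <= 0:
            raise ValueError("tract_mean must be positive")


@dataclass
class SimulationConfig:
    layout: GenomeLayout
    origins: list[PlantedOrigin]
    n_nuclei: int = 400
    incubation_scale: float = 1.0
    depth: float = 0.6  # mean reads per bp per library (30x at 50 bp reads)
    read_length: int = 50
    background: float = 0.005  # gradient cross-contamination fraction
    tract_core_fraction: float = 0.88  # deterministic share of the mean tract half-length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not 0 <= self.background < 0.5:
            raise ValueError("background must be in [0, 0.5)")
        if not 0 <= self.tract_core_fraction < 1:
            raise ValueError("tract_core_fraction must be in [0, 1)")

    @classmethod
    def default(cls, seed: int = 0, n_origins: int = 20) -> "SimulationConfig":
        """The package's reference study conditions.

        One ~200 kb chromosome carrying ``n_origins`` origins at 10 kb spacing
        with efficiencies uniform on [0.5, 1.0] and 3.4 kb mean tract
        half-length, sequenced at 30x per library. At these settings about
        half of the toy genome replicates, balancing the HL and LL pools so
        that per-million normalization leaves efficiency scores undistorted.
        """
        spacing = 10_000
        length = spacing * (n_origins + 1) - spacing // 2
        layout = GenomeLayout((("chrS", length),))
        rng = np.random.default_rng([seed, 7])
        effs = rng.uniform(0.5, 1.0, size=n_origins)
        origins = [
            PlantedOrigin("chrS", spacing * (k + 1), float(effs[k]), 3_400.0)
            for k in range(n_origins)
        ]
        return cls(layout=layout, origins=origins, seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "layout": {c: int(l) for c, l in self.layout.chromosomes},
            "origins": [
                {"chrom": o.chrom, "center": o.center,
                 "efficiency": o.efficiency, "tract_mean": o.tract_mean}
                for o in self.origins
            ],
            "n_nuclei": self.n_nuclei,
            "incubation_scale": self.incubation_scale,
            "depth": self.depth,
            "read_length": self.read_length,
            "background": self.background,
            "tract_core_fraction": self.tract_core_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        layout = GenomeLayout(tuple((c, int(l)) for c, l in doc["layout"].items()))
        origins = [PlantedOrigin(**o) for o in doc["origins"]]
        return cls(
            layout=layout,
            origins=origins,
            n_nuclei=int(doc.get("n_nuclei", 400)),
            incubation_scale=float(doc.get("incubation_scale", 1.0)),
            depth=float(doc.get("depth", 0.6)),
            read_length=int(doc.get("read_length", 50)),
            background=float(doc.get("background", 0.005)),
            tract_core_fraction=float(doc.get("tract_core_fraction", 0.88)),
            seed=int(doc["seed"]),
        )


@dataclass
class SimulationTruth:
    """Planted parameters plus the realized per-bp replicated fraction."""

    config: SimulationConfig
    fraction: dict[str, np.ndarray]  # f(x) per bp, in [0, 1]
    center_fractions: list[float]  # realized f at each planted centre

    def mean_fraction_over(self, chrom: str, start: int, end: int) -> float:
        return float(self.fraction[chrom][start:end].mean())

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"chrom": o.chrom, "center": o.center, "efficiency": o.efficiency,
             "tract_mean": o.tract_mean, "realized_fraction": cf}
            for o, cf in zip(self.config.origins, self.center_fractions)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_replicated_fraction(config: SimulationConfig) -> SimulationTruth:
    """Monte-Carlo realization of f(x) over the toy genome.

    Per nucleus, fired tracts are merged before accumulation so that a bp
    covered by several tracts of the same nucleus counts once.
    """
    rng = np.random.default_rng([config.seed, 1])
    scale = config.incubation_scale
    cov: dict[str, np.ndarray] = {
        chrom: np.zeros(L + 1, dtype=np.int32) for chrom, L in config.layout.chromosomes
    }
    by_chrom: dict[str, list[PlantedOrigin]] = {}
    for o in config.origins:
        by_chrom.setdefault(o.chrom, []).append(o)
    for chrom, origins in by_chrom.items():
        L = config.layout.length_of(chrom)
        diff = cov[chrom]
        n_org = len(origins)
        fires = rng.random((config.n_nuclei, n_org)) < np.array(
            [o.efficiency for o in origins]
        )
        means = np.array([o.tract_mean for o in origins]) * scale
        core = means * config.tract_core_fraction
        tail = means - core
        lefts = core + rng.exponential(tail, size=(config.n_nuclei, n_org))
        rights = core + rng.exponential(tail, size=(config.n_nuclei, n_org))
        centers = np.array([o.center for o in origins])
        for nuc in range(config.n_nuclei):
            idx = np.flatnonzero(fires[nuc])
            if idx.size == 0:
                continue
            starts = np.clip(centers[idx] - lefts[nuc, idx], 0, L).astype(np.int64)
            ends = np.clip(centers[idx] + rights[nuc, idx] + 1, 0, L).astype(np.int64)
            order = np.argsort(starts)
            cur_s, cur_e = None, None
            for s, e in zip(starts[order], ends[order]):
                if e <= s:
                    continue
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    diff[cur_s] += 1
                    diff[cur_e] -= 1
                    cur_s, cur_e = s, e
            if cur_s is not None:
                diff[cur_s] += 1
                diff[cur_e] -= 1
    fraction = {
        chrom: np.cumsum(diff[:-1]).astype(float) / config.n_nuclei
        for chrom, diff in cov.items()
    }
    center_fractions = [
        float(fraction[o.chrom][o.center]) for o in config.origins
    ]
    return SimulationTruth(config, fraction, center_fractions)


def emit_read_libraries(
    truth: SimulationTruth, config: SimulationConfig | None = None
) -> tuple[ReadSet, ReadSet]:
    """Draw the HL and LL read libraries from the realized replicated fraction."""
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 2])
    bg = config.background
    hl_starts: dict[str, np.ndarray] = {}
    ll_starts: dict[str, np.ndarray] = {}
    for chrom, L in config.layout.chromosomes:
        f = truth.fraction[chrom]
        hl_rate = config.depth * (f * (1 - bg) + (1 - f) * bg)
        ll_rate = config.depth * ((1 - f) * (1 - bg) + f * bg)
        max_start = L - config.read_length
        for rates, store in ((hl_rate, hl_starts), (ll_rate, ll_starts)):
            counts = rng.poisson(rates)
            starts = np.repeat(np.arange(L, dtype=np.int64), counts)
            store[chrom] = np.minimum(starts, max_start)
    hl = ReadSet(hl_starts, config.read_length, config.layout)
    ll = ReadSet(ll_starts, config.read_length, config.layout)
    return hl, ll


def generate_sequence(
    config: SimulationConfig,
    gc_background: float = 0.40,
    gc_at_origin: float = 0.65,
    skew_amplitude: float = 0.0,
) -> dict[str, str]:
    """Seeded random genome with elevated GC inside origin tracts.

    With ``skew_amplitude > 0`` a GC-skew sign switch is planted at each
    origin centre: the plus strand is C-rich to the left and G-rich to the
    right, so the skew profile crosses zero at the centre.
    """
    rng = np.random.default_rng([config.seed, 3])
    genome: dict[str, str] = {}
    for chrom, L in config.layout.chromosomes:
        gc = np.full(L, gc_background)
        side = np.zeros(L)
        for o in (x for x in config.origins if x.chrom == chrom):
            half = int(o.tract_mean * config.incubation_scale)
            lo, hi = max(0, o.center - half), min(L, o.center + half)
            gc[lo:hi] = gc_at_origin
            side[lo:o.center] = -1.0
            side[o.center:hi] = 1.0
        p_g = gc / 2 * (1 + skew_amplitude * side)
        p_c = gc / 2 * (1 - skew_amplitude * side)
        p_a = (1 - gc) / 2
        u = rng.random(L)
        codes = np.full(L, ord("T"), dtype=np.uint8)
        codes[u < p_g + p_c + p_a] = ord("A")
        codes[u < p_g + p_c] = ord("C")
        codes[u < p_g] = ord("G")
        genome[chrom] = codes.tobytes().decode("ascii")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_feature_benchmark(
    n: int = 2_000,
    n_features: int = 20,
    n_informative: int = 5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic feature table with a known smooth generative function.

    Predictors are iid standard normal; the response is an additive smooth
    function of the first ``n_informative`` predictors (linear, sine, tanh
    and quadratic terms), rescaled to an efficiency-like range and perturbed
    with Gaussian noise of sd ``noise_sd``. Returns the table and the names
    of the informative predictors.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    terms = [
        lambda x: x,
        lambda x: np.sin(x),
        lambda x: np.tanh(x),
        lambda x: 0.4 * x**2,
        lambda x: 0.8 * x + 0.3 * np.sin(x),
    ]
    signal = np.zeros(n)
    for k in range(n_informative):
        signal += terms[k % len(terms)](X[:, k])
    signal = (signal - signal.mean()) / signal.std()
    y_clean = 0.5 + 0.2 * signal
    y = np.clip(y_clean + rng.normal(0, noise_sd, size=n), 0.0, 1.0)
    names = [f"feat_{k + 1}" for k in range(n_features)]
    table = pd.DataFrame(X, columns=names)
    table[RESPONSE_COLUMN] = y
    table.attrs["y_clean"] = y_clean
    return table, names[:n_informative]


RESPONSE_COLUMN = "efficiency"
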