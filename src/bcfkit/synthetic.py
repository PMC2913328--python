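"""Deterministic synthetic datasets and toy structures.

The generator emulates the statistical shape of a logP-driven BCF
dataset: logP uniform over a range, logBCF linear in logP plus Gaussian
noise, and an optional second experimental measurement per compound to
mimic replicate variability between data sources.  Placeholder SMILES
come from a fixed pool and are deliberately decoupled from the numeric
fields, so statistical tests are exact while :func:`fixture_structures`
provides the structure-aware test surface with hand-verified fragment
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .chemdata import CompoundRecord, ConfigError, Dataset, parse_structure

# Defaults follow the published univariate MLOGP model (slope 0.555,
# intercept 0.117) with noise at the ~0.5 log-unit level both model SDEP
# and experimental variability sit at; logP spans the 0-9 range typical
# of a bioconcentration dataset.
DEFAULT_SLOPE = 0.555
DEFAULT_INTERCEPT = 0.117
DEFAULT_NOISE_SD = 0.5
DEFAULT_LOGP_RANGE = (0.0, 9.0)
DEFAULT_REPLICATE_PROB = 0.3
DEFAULT_REPLICATE_SD = 0.45

# The canonical dataset was split 370 : 93 : 172 = 635 into training,
# first validation and second (external) validation sets.
SPLIT_PROPORTIONS = (370, 93, 172)

_SMILES_POOL = (
    "CCCCCC", "CCCCCCCC", "CCCCCCCCCC", "c1ccccc1", "Cc1ccccc1",
    "c1ccc2ccccc2c1", "CCCCCCCCCCCC", "CC(C)CCCC", "c1ccc(-c2ccccc2)cc1",
    "CCCCCCCCCCCCCC",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic logP-logBCF generator."""

    n: int = 635
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD
    logp_range: tuple[float, float] = DEFAULT_LOGP_RANGE
    replicate_prob: float = DEFAULT_REPLICATE_PROB
    replicate_sd: float = DEFAULT_REPLICATE_SD
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ConfigError("noise_sd and replicate_sd must be non-negative")
        lo, hi = self.logp_range
        if not lo < hi:
            raise ConfigError(f"logp_range must satisfy low < high, got {self.logp_range}")
        if not 0.0 <= self.replicate_prob <= 1.0:
            raise ConfigError("replicate_prob must be in [0, 1]")


def generate_dataset(config: GeneratorConfig, split_label: str = "unlabelled") -> Dataset:
    """Generate ``config.n`` compound records, reproducibly from the seed.

    Per record: logP ~ U(logp_range); true logBCF = slope*logP +
    intercept; one experimental value = true + N(0, noise_sd), with
    probability ``replicate_prob`` a second value ~ N(first,
    replicate_sd).  ``predicted_logbcf`` is set to the noiseless model
    value, so prediction residuals equal the generating noise.  A small
    descriptor vector (logp plus two seeded auxiliary descriptors) makes
    records usable by the similarity machinery.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.logp_range
    logp = rng.uniform(lo, hi, size=config.n)
    true = config.slope * logp + config.intercept
    first = true + rng.normal(0.0, config.noise_sd, size=config.n)
    has_rep = rng.random(config.n) < config.replicate_prob
    second = rng.normal(first, config.replicate_sd)
    aux1 = logp + rng.normal(0.0, 1.0, size=config.n)
    aux2 = rng.normal(0.0, 1.0, size=config.n)

    records = []
    width = len(str(config.n))
    for i in range(config.n):
        values = [float(first[i])]
        if has_rep[i]:
            values.append(float(second[i]))
        records.append(
            CompoundRecord(
                id=f"syn-{i + 1:0{width}d}",
                smiles=_SMILES_POOL[i % len(_SMILES_POOL)],
                exp_logbcf=values,
                logp={"synthetic": float(logp[i])},
                predicted_logbcf=float(true[i]),
                descriptors={
                    "logp": float(logp[i]),
                    "aux1": float(aux1[i]),
                    "aux2": float(aux2[i]),
                },
            )
        )
    return Dataset(records=records, split_label=split_label)


def apportion(n: int, weights=SPLIT_PROPORTIONS) -> list[int]:
    """Largest-remainder apportionment of n items across the weights."""
    total = sum(weights)
    quotas = [n * w / total for w in weights]
    floors = [int(q) for q in quotas]
    shortfall = n - sum(floors)
    order = sorted(range(len(weights)), key=lambda i: quotas[i] - floors[i], reverse=True)
    for i in order[:shortfall]:
        floors[i] += 1
    return floors


def make_three_splits(config: GeneratorConfig) -> tuple[Dataset, Dataset, Dataset]:
    """Disjoint training / first-validation / second-validation datasets
    in the canonical 370:93:172 proportion, scaled to ``config.n``."""
    if config.n < 10:
        raise ConfigError(f"need n >= 10 to form three splits, got {config.n}")
    full = generate_dataset(config)
    n_train, n_val1, n_val2 = apportion(config.n)
    recs = full.records
    return (
        Dataset(records=recs[:n_train], split_label="training"),
        Dataset(records=recs[n_train:n_train + n_val1], split_label="first_validation"),
        Dataset(records=recs[n_train + n_val1:], split_label="second_validation"),
    )


# Hand-verified counts for the default fragment-rule SMARTS, keyed by
# pattern.  [Cl,Br]a matches a halogen bonded to an aromatic atom; the
# count is over unique atom sets.
_FIXTURES = (
    ("benzene", {"[Cl]": 0, "O[a]": 0, "[Cl,Br]a": 0, "[Si]": 0}),
    ("hexachlorobenzene", {"[Cl]": 6, "O[a]": 0, "[Cl,Br]a": 6, "[Si]": 0}),
    ("pentachlorophenol", {"[Cl]": 5, "O[a]": 1, "[Cl,Br]a": 5, "[Si]": 0}),
    ("246-trichloroanisole", {"[Cl]": 3, "O[a]": 1, "[Cl,Br]a": 3, "[Si]": 0}),
    ("246-trichlorophenol", {"[Cl]": 3, "O[a]": 1, "[Cl,Br]a": 3, "[Si]": 0}),
    ("carbon-disulfide", {"[Cl]": 0, "O[a]": 0, "[Cl,Br]a": 0, "[Si]": 0}),
    ("octamethylcyclotetrasiloxane", {"[Cl]": 0, "O[a]": 0, "[Cl,Br]a": 0, "[Si]": 4}),
    ("dodecanol", {"[Cl]": 0, "O[a]": 0, "[Cl,Br]a": 0, "[Si]": 0}),
)


def fixture_structures() -> list[tuple[str, str, dict[str, int]]]:
    """Curated (name, smiles, expected_fragment_counts) triples.

    Includes a plain aromatic, highly chlorinated aromatics that trigger
    the chlorine-count and aromatic-oxygen-plus-halogens alerts, the two
    classic out-of-domain cases (carbon disulfide, a cyclic siloxane),
    and a long-chain alcohol.  Counts were verified by hand from the
    structures.
    """
    smiles_by_id = {}
    payload = (
        resources.files("bcfkit").joinpath("data/fixture_structures.smi").read_text()
    )
    for line in payload.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi, name = line.split("\t")
        smiles_by_id[name] = smi
    return [(name, smiles_by_id[name], dict(counts)) for name, counts in _FIXTURES]


def fixture_dataset() -> Dataset:
    """The fixture structures as a parsed Dataset (no numeric fields)."""
    records = [
        CompoundRecord(id=name, smiles=smi, structure=parse_structure(smi))
        for name, smi, _ in fixture_structures()
    ]
    return Dataset(records=records)
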