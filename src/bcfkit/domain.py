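"""Applicability-domain battery: descriptor ranges, structural alerts,
similarity neighbors.

A QSAR prediction is only trustworthy inside the model's applicability
domain (AD).  Three independent checks are combined here:

1. *Descriptor ranges* — each descriptor of the query must fall inside
   the [min, max] observed on the training set; any excursion puts the
   compound out of domain.
2. *Structural alerts* — SMARTS fragment rules mined from compounds the
   model mispredicted by more than a log unit (e.g. highly chlorinated
   aromatics); a triggered rule is a warning.
3. *Similarity neighbors* — the six training compounds most similar to
   the query, each reported with its experimental and predicted logBCF
   so the user sees the local error directly.  A best similarity below
   0.5, or a mean neighbor error above 1 log unit, is a warning.

The verdict plus every contributing reason is rendered as a per-compound
result sheet (text and JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from sklearn.base import BaseEstimator

from .chemdata import CompoundRecord, Dataset, DataError, Structure, mean_exp_logbcf

SIMILARITY_WARN_THRESHOLD = 0.5
NEIGHBOR_ERROR_WARN_THRESHOLD = 1.0  # log units; the rule-mining cutoff
DEFAULT_K = 6


class PatternError(ValueError):
    """A SMARTS pattern failed to compile at rule-load time."""


# ---------------------------------------------------------------------------
# First approach: descriptor ranges
# ---------------------------------------------------------------------------

DescriptorRanges = dict[str, tuple[float, float]]


def learn_ranges(training: Dataset, descriptor_names: list[str]) -> DescriptorRanges:
    """Per-descriptor [min, max] over the training set.

    Every training record must carry every named descriptor.
    """
    ranges: DescriptorRanges = {}
    for name in descriptor_names:
        values = []
        for rec in training:
            if rec.descriptors is None or name not in rec.descriptors:
                raise DataError(f"record {rec.id} lacks descriptor {name!r}")
            values.append(rec.descriptors[name])
        ranges[name] = (min(values), max(values))
    return ranges


def check_ranges(record: CompoundRecord, ranges: DescriptorRanges) -> list[str]:
    """Names of descriptors outside their training range (closed interval:
    a value exactly at the boundary is inside)."""
    out = []
    for name, (lo, hi) in ranges.items():
        if record.descriptors is None or name not in record.descriptors:
            raise DataError(f"record {record.id} lacks descriptor {name!r}")
        v = record.descriptors[name]
        if v < lo or v > hi:
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Second approach: SMARTS fragment rules
# ---------------------------------------------------------------------------


@dataclass
class FragmentRule:
    """A structural alert: SMARTS pattern(s) with count constraints.

    ``min_counts[i]`` is the minimum number of distinct matches required
    of ``smarts_list[i]``.  A plain count rule has one pattern ("at least
    six chlorine atoms" is ``["[Cl]"]`` with min count 6); a conjunctive
    rule requires every pattern to meet its own minimum (aromatic-bound
    oxygen AND at least three aromatic-bound halogens).
    """

    rule_id: str
    smarts_list: list[str]
    min_counts: list[int] = field(default_factory=list)
    conjunctive: bool = False
    description: str = ""
    template: bool = False

    def __post_init__(self):
        if not self.smarts_list:
            raise PatternError(f"rule {self.rule_id}: empty SMARTS list")
        if not self.min_counts:
            self.min_counts = [1] * len(self.smarts_list)
        if len(self.min_counts) != len(self.smarts_list):
            raise PatternError(
                f"rule {self.rule_id}: {len(self.min_counts)} min_counts for "
                f"{len(self.smarts_list)} patterns"
            )
        if any(m < 1 for m in self.min_counts):
            raise PatternError(f"rule {self.rule_id}: min_count must be >= 1")
        self._patterns = []
        for s in self.smarts_list:
            patt = Chem.MolFromSmarts(s)
            if patt is None:
                raise PatternError(f"rule {self.rule_id}: invalid SMARTS {s!r}")
            self._patterns.append(patt)

    @property
    def min_count(self) -> int:
        """Minimum matches of the first pattern (the headline count)."""
        return self.min_counts[0]

    @property
    def patterns(self):
        return list(self._patterns)


def count_fragment(structure: Structure, smarts) -> int:
    """Number of distinct substructure matches (unique atom sets).

    Atom-set semantics, not embeddings: "[Cl]" on hexachlorobenzene
    counts 6 chlorine atoms, and a symmetric pattern never double-counts
    the atoms it matched in a different order.
    """
    if isinstance(smarts, str):
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise PatternError(f"invalid SMARTS {smarts!r}")
    else:
        patt = smarts
    matches = structure.mol.GetSubstructMatches(patt, uniquify=True)
    return len({frozenset(m) for m in matches})


def match_rule(structure: Structure, rule: FragmentRule) -> bool:
    """True iff the first pattern reaches its minimum count and, for a
    conjunctive rule, every additional pattern reaches its own."""
    counts = [count_fragment(structure, p) for p in rule.patterns]
    if counts[0] < rule.min_counts[0]:
        return False
    if rule.conjunctive:
        return all(c >= m for c, m in zip(counts[1:], rule.min_counts[1:]))
    return True


def screen_rules(structure: Structure, rules: list[FragmentRule]) -> list[str]:
    """Ids of all triggered rules, in rule-file order."""
    return [r.rule_id for r in rules if match_rule(structure, r)]


def load_rules(path=None) -> list[FragmentRule]:
    """Load fragment rules from a JSON array; default is the packaged set.

    Every SMARTS is compiled at load time so a bad pattern fails here,
    never during matching.
    """
    if path is None:
        payload = (
            resources.files("bcfkit").joinpath("data/fragment_rules.json").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            payload = fh.read()
    return [FragmentRule(**entry) for entry in json.loads(payload)]


# ---------------------------------------------------------------------------
# Fallback descriptor backend
# ---------------------------------------------------------------------------

FALLBACK_DESCRIPTORS = (
    "mol_weight",
    "heavy_atoms",
    "halogen_count",
    "aromatic_atoms",
    "clogp",
    "hbond_donors",
    "hbond_acceptors",
    "rotatable_bonds",
)

_HALOGENS = {9, 17, 35, 53}


def compute_descriptors(structure: Structure) -> dict[str, float]:
    """Eight structure-derived descriptors for compounds arriving without
    a descriptor vector: molecular weight, heavy-atom count, halogen
    count, aromatic-atom count, Crippen calculated logP, H-bond
    donor/acceptor counts, rotatable bonds."""
    mol = structure.mol
    return {
        "mol_weight": float(Descriptors.MolWt(mol)),
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "halogen_count": float(
            sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in _HALOGENS)
        ),
        "aromatic_atoms": float(structure.num_aromatic_atoms),
        "clogp": float(Crippen.MolLogP(mol)),
        "hbond_donors": float(Lipinski.NumHDonors(mol)),
        "hbond_acceptors": float(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
    }


# ---------------------------------------------------------------------------
# Third approach: similarity and neighbors
# ---------------------------------------------------------------------------


@dataclass
class DescriptorScaling:
    """Per-descriptor min-max scaling fitted on a reference dataset.

    Query values are clipped into [0, 1] after scaling, so a query far
    outside the reference box saturates at the box surface — the range
    check (approach 1), not the similarity score, is responsible for
    flagging extrapolation.
    """

    names: list[str]
    mins: np.ndarray
    ptps: np.ndarray  # max - min; zero-width descriptors scale to 0

    @classmethod
    def fit(cls, reference: Dataset, names: list[str]) -> "DescriptorScaling":
        matrix = _descriptor_matrix(reference, names)
        mins = matrix.min(axis=0)
        ptps = matrix.max(axis=0) - mins
        return cls(names=list(names), mins=mins, ptps=ptps)

    def scale(self, vector: dict[str, float]) -> np.ndarray:
        missing = [n for n in self.names if n not in vector]
        if missing:
            raise DataError(f"descriptor vector lacks {missing}")
        raw = np.asarray([vector[n] for n in self.names], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(self.ptps > 0, (raw - self.mins) / np.where(self.ptps > 0, self.ptps, 1.0), 0.0)
        return np.clip(scaled, 0.0, 1.0)


def _descriptor_matrix(dataset: Dataset, names: list[str]) -> np.ndarray:
    rows = []
    for rec in dataset:
        if rec.descriptors is None:
            raise DataError(f"record {rec.id} has no descriptor vector")
        missing = [n for n in names if n not in rec.descriptors]
        if missing:
            raise DataError(f"record {rec.id} lacks descriptors {missing}")
        rows.append([rec.descriptors[n] for n in names])
    return np.asarray(rows, dtype=float)


def similarity_index(
    desc_a: dict[str, float],
    desc_b: dict[str, float],
    scaling: DescriptorScaling,
) -> float:
    """Similarity in [0, 1] between two descriptor vectors.

    Both vectors are min-max scaled into the reference unit hypercube,
    then similarity = 1 − (Euclidean distance / √d) with d the number of
    descriptors.  Identical vectors score exactly 1; opposite corners of
    the hypercube score 0.  Symmetric by construction.
    """
    if set(desc_a) < set(scaling.names) or set(desc_b) < set(scaling.names):
        raise DataError("descriptor vectors must cover the scaled descriptor names")
    a = scaling.scale(desc_a)
    b = scaling.scale(desc_b)
    d = len(scaling.names)
    return float(1.0 - np.linalg.norm(a - b) / np.sqrt(d))


@dataclass
class NeighborHit:
    """One similar reference compound with its local prediction error."""

    neighbor_id: str
    similarity: float
    exp_logbcf: float
    predicted_logbcf: float

    @property
    def abs_error(self) -> float:
        return abs(self.exp_logbcf - self.predicted_logbcf)


def find_neighbors(
    query: CompoundRecord,
    reference: Dataset,
    scaling: DescriptorScaling,
    k: int = DEFAULT_K,
) -> tuple[list[NeighborHit], bool]:
    """Top-k reference compounds by similarity to the query.

    Ties break by reference order (stable sort).  Returns the hits plus a
    short-list flag set when the reference holds fewer than k compounds.
    """
    if query.descriptors is None:
        raise DataError(f"query {query.id} has no descriptor vector")
    hits = []
    for rec in reference:
        if rec.descriptors is None:
            raise DataError(f"reference record {rec.id} has no descriptor vector")
        if not rec.exp_logbcf or rec.predicted_logbcf is None:
            raise DataError(
                f"reference record {rec.id} needs experimental and predicted logBCF"
            )
        sim = similarity_index(query.descriptors, rec.descriptors, scaling)
        hits.append(
            NeighborHit(
                neighbor_id=rec.id,
                similarity=sim,
                exp_logbcf=mean_exp_logbcf(rec),
                predicted_logbcf=rec.predicted_logbcf,
            )
        )
    # stable sort on -similarity keeps reference order among ties
    hits.sort(key=lambda h: -h.similarity)
    short = len(hits) < k
    return hits[:k], short


# ---------------------------------------------------------------------------
# Verdict and reporting
# ---------------------------------------------------------------------------

VERDICTS = ("in_domain", "warning", "out_of_domain")


@dataclass
class DomainReport:
    """Combined outcome of the three AD checks for one compound."""

    out_of_range_descriptors: list[str] = field(default_factory=list)
    triggered_rules: list[str] = field(default_factory=list)
    neighbors: list[NeighborHit] = field(default_factory=list)
    short_neighbor_list: bool = False
    verdict: str = "in_domain"
    reasons: list[str] = field(default_factory=list)

    @property
    def max_similarity(self) -> float:
        return max((h.similarity for h in self.neighbors), default=0.0)

    @property
    def mean_neighbor_error(self) -> float:
        if not self.neighbors:
            return 0.0
        return sum(h.abs_error for h in self.neighbors) / len(self.neighbors)

    def to_dict(self) -> dict:
        payload = asdict(self)
        for h, hit in zip(payload["neighbors"], self.neighbors):
            h["abs_error"] = hit.abs_error
        payload["max_similarity"] = self.max_similarity
        payload["mean_neighbor_error"] = self.mean_neighbor_error
        return payload


def domain_verdict(
    range_flags: list[str],
    triggered_rules: list[str],
    neighbors: list[NeighborHit],
    short_neighbor_list: bool = False,
    similarity_threshold: float = SIMILARITY_WARN_THRESHOLD,
    neighbor_error_threshold: float = NEIGHBOR_ERROR_WARN_THRESHOLD,
) -> DomainReport:
    """Combine the three checks into a verdict.

    Any out-of-range descriptor -> out_of_domain.  A triggered rule, a
    best similarity below the threshold, or a mean neighbor error above
    the threshold -> warning.  Every contributing factor is listed in
    ``reasons``.
    """
    report = DomainReport(
        out_of_range_descriptors=list(range_flags),
        triggered_rules=list(triggered_rules),
        neighbors=list(neighbors),
        short_neighbor_list=short_neighbor_list,
    )
    reasons = []
    if range_flags:
        reasons.append(
            "descriptors out of training range: " + ", ".join(range_flags)
        )
    for rid in triggered_rules:
        reasons.append(f"structural alert triggered: rule {rid}")
    if neighbors and report.max_similarity < similarity_threshold:
        reasons.append(
            f"low similarity: best neighbor {report.max_similarity:.3f} < "
            f"{similarity_threshold}"
        )
    if neighbors and report.mean_neighbor_error > neighbor_error_threshold:
        reasons.append(
            f"poorly predicted neighborhood: mean |error| "
            f"{report.mean_neighbor_error:.2f} > {neighbor_error_threshold} log units"
        )
    if short_neighbor_list:
        reasons.append("reference set smaller than requested neighbor count")

    report.reasons = reasons
    if range_flags:
        report.verdict = "out_of_domain"
    elif reasons:
        report.verdict = "warning"
    else:
        report.verdict = "in_domain"
    return report


class ApplicabilityDomain(BaseEstimator):
    """Fitted AD battery: learns ranges and similarity scaling from a
    training set, then assesses query compounds.

    Parameters
    ----------
    descriptor_names : list of str, optional
        Descriptors to use; default is the eight-descriptor fallback set
        (computed from structure when a record carries none).
    rules : list of FragmentRule, optional
        Structural alerts; default is the packaged rule file.
    k : int, default=6
        Neighbors to report.
    similarity_threshold : float, default=0.5
    neighbor_error_threshold : float, default=1.0

    Attributes
    ----------
    ranges_ : dict name -> (min, max)
    scaling_ : DescriptorScaling
    reference_ : Dataset used for neighbor retrieval.
    """

    def __init__(
        self,
        descriptor_names: list[str] | None = None,
        rules: list[FragmentRule] | None = None,
        k: int = DEFAULT_K,
        similarity_threshold: float = SIMILARITY_WARN_THRESHOLD,
        neighbor_error_threshold: float = NEIGHBOR_ERROR_WARN_THRESHOLD,
    ):
        self.descriptor_names = descriptor_names
        self.rules = rules
        self.k = k
        self.similarity_threshold = similarity_threshold
        self.neighbor_error_threshold = neighbor_error_threshold

    def fit(self, training: Dataset, y=None):
        names = list(self.descriptor_names or FALLBACK_DESCRIPTORS)
        training = _ensure_descriptors(training, names)
        self.descriptor_names_ = names
        self.rules_ = self.rules if self.rules is not None else load_rules()
        self.ranges_ = learn_ranges(training, names)
        self.scaling_ = DescriptorScaling.fit(training, names)
        self.reference_ = training
        return self

    def assess(self, record: CompoundRecord) -> DomainReport:
        record = _ensure_record_descriptors(record, self.descriptor_names_)
        range_flags = check_ranges(record, self.ranges_)
        if record.structure is not None:
            triggered = screen_rules(record.structure, self.rules_)
        else:
            triggered = []
        neighbors, short = find_neighbors(
            record, self.reference_, self.scaling_, k=self.k
        )
        return domain_verdict(
            range_flags,
            triggered,
            neighbors,
            short_neighbor_list=short,
            similarity_threshold=self.similarity_threshold,
            neighbor_error_threshold=self.neighbor_error_threshold,
        )

    def transform(self, dataset: Dataset) -> list[DomainReport]:
        return [self.assess(rec) for rec in dataset]


def _ensure_record_descriptors(
    record: CompoundRecord, names: list[str]
) -> CompoundRecord:
    if record.descriptors is not None and all(n in record.descriptors for n in names):
        return record
    if record.structure is None:
        raise DataError(
            f"record {record.id}: no descriptors and no parsed structure to "
            "compute the fallback set from"
        )
    computed = compute_descriptors(record.structure)
    merged = {**computed, **(record.descriptors or {})}
    record.descriptors = merged
    return record


def _ensure_descriptors(dataset: Dataset, names: list[str]) -> Dataset:
    for rec in dataset:
        _ensure_record_descriptors(rec, names)
    return dataset


def render_result_sheet(
    record: CompoundRecord,
    prediction,
    report: DomainReport,
    rules: list[FragmentRule] | None = None,
) -> str:
    """Human-readable per-compound result sheet.

    Shows identity, raw and offset-adjusted prediction, regulatory class,
    each AD check outcome, and the similar reference compounds with their
    experimental vs predicted values.  A JSON twin is available through
    :func:`result_sheet_json`.
    """
    rule_desc = {r.rule_id: r.description for r in (rules or [])}
    lines = [
        "=" * 64,
        f"Compound: {record.id}" + (f"  (CAS {record.cas})" if record.cas else ""),
        f"SMILES:   {record.smiles}",
        "-" * 64,
        f"Raw predicted logBCF:      {prediction.raw_logbcf:.2f}",
        f"Adjusted logBCF:           {prediction.adjusted_logbcf:.2f}"
        + ("  (conservative offset applied)" if prediction.offset_applied else ""),
        f"Regulatory class:          {prediction.bcf_class}",
        "-" * 64,
        "Applicability domain:",
    ]
    if report.out_of_range_descriptors:
        lines.append(
            "  [1] descriptor ranges:   OUT OF RANGE: "
            + ", ".join(report.out_of_range_descriptors)
        )
    else:
        lines.append("  [1] descriptor ranges:   ok")
    if report.triggered_rules:
        for rid in report.triggered_rules:
            desc = rule_desc.get(rid, "")
            lines.append(f"  [2] structural alert:    rule {rid}" + (f" — {desc}" if desc else ""))
    else:
        lines.append("  [2] structural alerts:   none triggered")
    lines.append(
        f"  [3] best similarity:     {report.max_similarity:.3f}"
        + ("  (below 0.5)" if report.max_similarity < SIMILARITY_WARN_THRESHOLD else "")
    )
    verdict_label = report.verdict.replace("_", " ")
    lines.append(f"  Verdict: {verdict_label}")
    for reason in report.reasons:
        lines.append(f"    - {reason}")
    lines.append("-" * 64)
    n = len(report.neighbors)
    header = f"Most similar reference compounds ({n})"
    if report.short_neighbor_list:
        header += "  [fewer than requested: short reference set]"
    lines.append(header)
    lines.append(f"  {'id':<14}{'similarity':>11}{'exp logBCF':>12}{'pred logBCF':>13}{'|error|':>9}")
    for h in report.neighbors:
        lines.append(
            f"  {h.neighbor_id:<14}{h.similarity:>11.3f}{h.exp_logbcf:>12.2f}"
            f"{h.predicted_logbcf:>13.2f}{h.abs_error:>9.2f}"
        )
    lines.append("=" * 64)
    return "\n".join(lines)


def result_sheet_json(record: CompoundRecord, prediction, report: DomainReport) -> str:
    """Machine-readable twin of the text result sheet."""
    payload = {
        "id": record.id,
        "cas": record.cas,
        "smiles": record.smiles,
        "raw_logbcf": prediction.raw_logbcf,
        "adjusted_logbcf": prediction.adjusted_logbcf,
        "bcf_class": str(prediction.bcf_class),
        "offset_applied": prediction.offset_applied,
        "domain": report.to_dict(),
    }
    return json.dumps(payload, indent=2)
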