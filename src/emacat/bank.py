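"""Item banks for multidimensional graded-response adaptive testing.

An item bank is the precalibrated pool a multidimensional CAT selects from:
each item carries a discrimination vector over the m correlated latent
domains (m = 14 by default: 12 risk domains plus passive and active suicidal
ideation) and four ordered category intercepts for 5-point Likert responses.
The bank also carries the joint prior correlation matrix of the latent
domains, which the scoring module uses as the multivariate-normal prior and
the adaptive module uses as the Bayesian D-optimality base precision.

This module defines the data model, validates its invariants, reads and
writes CSV/JSON interchange formats, assembles the joint 14-domain prior
from its calibrated blocks, and generates synthetic banks that mimic the
published bank shape (189 risk items across 12 domains, 9 + 9 suicidal
ideation items) so the whole engine is testable without access to the
calibrated item pool.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_CATEGORIES = 5  # 5-point Likert responses, so K - 1 = 4 intercepts
N_THRESHOLDS = N_CATEGORIES - 1

#: Default latent-domain roster: 12 risk domains followed by the two
#: suicidal-ideation (SI) factors.  Order fixes the meaning of index g in
#: every discrimination vector and covariance matrix.
DEFAULT_DOMAIN_NAMES: tuple[str, ...] = (
    "humiliation",
    "loneliness",
    "anger",
    "pain",
    "negative_urgency",
    "defeat",
    "entrapment",
    "distress_tolerance",
    "perceived_burdensomeness",
    "thwarted_belongingness",
    "hope",
    "aggression",
    "passive_si",
    "active_si",
)

DEFAULT_DOMAIN_ROLES: tuple[str, ...] = ("risk",) * 12 + ("passive_SI", "active_SI")

#: Calibrated interfactor correlations among the 12 risk domains
#: (order matches DEFAULT_DOMAIN_NAMES[:12]).
RISK_DOMAIN_CORRELATIONS: np.ndarray = np.array(
    [
        [1.000, 0.560, 0.561, 0.441, 0.478, 0.487, 0.540, 0.580, 0.541, 0.160, 0.051, 0.383],
        [0.560, 1.000, 0.611, 0.612, 0.415, 0.739, 0.733, 0.600, 0.695, 0.359, 0.253, 0.316],
        [0.561, 0.611, 1.000, 0.458, 0.588, 0.581, 0.620, 0.617, 0.532, 0.179, 0.094, 0.443],
        [0.441, 0.612, 0.458, 1.000, 0.000, 0.674, 0.660, 0.573, 0.612, 0.245, 0.234, 0.394],
        [0.478, 0.415, 0.588, 0.000, 1.000, 0.336, 0.373, 0.457, 0.407, 0.072, 0.023, 0.252],
        [0.487, 0.739, 0.581, 0.674, 0.336, 1.000, 0.780, 0.620, 0.683, 0.334, 0.355, 0.299],
        [0.540, 0.733, 0.620, 0.660, 0.373, 0.780, 1.000, 0.649, 0.713, 0.335, 0.288, 0.335],
        [0.580, 0.600, 0.617, 0.573, 0.457, 0.620, 0.649, 1.000, 0.609, 0.129, 0.068, 0.349],
        [0.541, 0.695, 0.532, 0.612, 0.407, 0.683, 0.713, 0.609, 1.000, 0.342, 0.291, 0.439],
        [0.160, 0.359, 0.179, 0.245, 0.072, 0.334, 0.335, 0.129, 0.342, 1.000, 0.646, 0.144],
        [0.051, 0.253, 0.094, 0.234, 0.023, 0.355, 0.288, 0.068, 0.291, 0.646, 1.000, 0.022],
        [0.383, 0.316, 0.443, 0.394, 0.252, 0.299, 0.335, 0.349, 0.439, 0.144, 0.022, 1.000],
    ]
)

#: Calibrated correlation between the passive and active SI factors.
SI_CORRELATION = 0.92

#: Number of items whose strongest loading falls on each risk domain in the
#: published bank (sums to 189), followed by the 9 + 9 SI items.
DEFAULT_PRIMARY_COUNTS: dict[str, int] = {
    "humiliation": 32,
    "loneliness": 30,
    "anger": 22,
    "pain": 13,
    "negative_urgency": 11,
    "defeat": 14,
    "entrapment": 16,
    "distress_tolerance": 14,
    "perceived_burdensomeness": 14,
    "thwarted_belongingness": 7,
    "hope": 12,
    "aggression": 4,
    "passive_si": 9,
    "active_si": 9,
}

PD_EIGENVALUE_FLOOR = 1e-4


class BankValidationError(ValueError):
    """Raised when an item bank violates its structural invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "item bank failed validation:\n  - " + "\n  - ".join(self.violations)
        )


class BankParseError(ValueError):
    """Raised when a bank file cannot be parsed; names the offending row/field."""


@dataclass(frozen=True)
class DomainSpec:
    """One latent domain: integer index, label, and role in the instrument."""

    domain_id: int
    name: str
    role: str  # "risk" | "passive_SI" | "active_SI"


@dataclass
class ItemParameters:
    """Calibrated parameters of one polytomous item.

    ``a`` is the discrimination vector over the m domains (sparse: nonzero
    only where the item loads); ``d`` holds the K-1 = 4 cumulative-logit
    intercepts, strictly decreasing so all five category probabilities are
    positive.  ``primary_domain`` is the domain of the strongest |loading|.
    """

    item_id: str
    prompt: str
    a: np.ndarray
    d: np.ndarray
    primary_domain: int

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.d = np.asarray(self.d, dtype=float)

    def violations(self, n_domains: int | None = None) -> list[str]:
        """Return a description of every invariant this item breaks."""
        out: list[str] = []
        if n_domains is not None and self.a.shape != (n_domains,):
            out.append(
                f"item {self.item_id!r}: discrimination vector has length "
                f"{self.a.size}, expected {n_domains}"
            )
            return out
        if self.d.shape != (N_THRESHOLDS,):
            out.append(
                f"item {self.item_id!r}: expected {N_THRESHOLDS} intercepts, "
                f"got {self.d.size}"
            )
        elif not np.all(np.diff(self.d) < 0):
            out.append(
                f"item {self.item_id!r}: intercepts d must be strictly "
                f"decreasing, got {self.d.tolist()}"
            )
        if not np.any(self.a != 0):
            out.append(f"item {self.item_id!r}: all-zero discrimination vector")
        elif self.primary_domain != int(np.argmax(np.abs(self.a))):
            out.append(
                f"item {self.item_id!r}: primary_domain={self.primary_domain} "
                f"inconsistent with argmax |a|={int(np.argmax(np.abs(self.a)))}"
            )
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.d))):
            out.append(f"item {self.item_id!r}: non-finite parameter")
        return out


@dataclass
class ItemBank:
    """The full calibrated pool plus the joint prior correlation matrix."""

    items: list[ItemParameters]
    domains: list[DomainSpec]
    prior_correlation: np.ndarray

    def __post_init__(self) -> None:
        self.prior_correlation = np.asarray(self.prior_correlation, dtype=float)
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._by_id: dict[str, ItemParameters] | None = None

    # -- convenience accessors -------------------------------------------
    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> ItemParameters:
        if self._by_id is None:
            self._by_id = {it.item_id: it for it in self.items}
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked (A, D, primary) arrays for vectorized computation.

        A is (J, m) discriminations, D is (J, 4) intercepts, primary is (J,)
        primary-domain indices, all in bank item order.
        """
        if self._arrays is None:
            A = np.stack([it.a for it in self.items])
            D = np.stack([it.d for it in self.items])
            primary = np.array([it.primary_domain for it in self.items])
            self._arrays = (A, D, primary)
        return self._arrays

    def items_for_domain(self, domain_id: int) -> list[ItemParameters]:
        return [it for it in self.items if it.primary_domain == domain_id]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_bank(bank: ItemBank) -> list[str]:
    """Return a list of invariant violations; empty iff the bank is valid."""
    out: list[str] = []
    m = bank.n_domains

    names = [d.name for d in bank.domains]
    if len(set(names)) != len(names):
        out.append("duplicate domain names")
    if [d.domain_id for d in bank.domains] != list(range(m)):
        out.append("domain_ids must be 0..m-1 in order")

    ids = bank.item_ids
    seen: set[str] = set()
    for iid in ids:
        if iid in seen:
            out.append(f"duplicate item_id {iid!r}")
        seen.add(iid)

    for it in bank.items:
        out.extend(it.violations(n_domains=m))

    R = bank.prior_correlation
    if R.shape != (m, m):
        out.append(f"prior_correlation has shape {R.shape}, expected ({m}, {m})")
    else:
        if not np.allclose(R, R.T, atol=1e-10):
            out.append("prior_correlation not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            out.append("prior_correlation diagonal not 1")
        if np.any(np.abs(R) > 1 + 1e-10):
            out.append("prior_correlation has entries outside [-1, 1]")
        if np.allclose(R, R.T, atol=1e-10):
            min_eig = float(np.linalg.eigvalsh((R + R.T) / 2).min())
            if min_eig <= 0:
                out.append(
                    f"prior_correlation not positive definite "
                    f"(min eigenvalue {min_eig:.3e})"
                )

    covered = {it.primary_domain for it in bank.items}
    for d in bank.domains:
        if d.domain_id not in covered:
            out.append(f"domain {d.name!r} has no primary item")

    return out


def _require_valid(bank: ItemBank) -> ItemBank:
    violations = validate_bank(bank)
    if violations:
        raise BankValidationError(violations)
    return bank


# ---------------------------------------------------------------------------
# Prior covariance assembly
# ---------------------------------------------------------------------------

def nearest_pd_correlation(
    R: np.ndarray, floor: float = PD_EIGENVALUE_FLOOR
) -> tuple[np.ndarray, bool]:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result rescaled to unit
    diagonal.  Deterministic and order-independent.  Returns the repaired
    matrix and a flag saying whether any repair was needed.
    """
    R = np.asarray(R, dtype=float)
    sym = (R + R.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor and np.allclose(np.diag(sym), 1.0, atol=1e-12):
        return sym, False
    clipped = np.maximum(vals, floor)
    fixed = (vecs * clipped) @ vecs.T
    scale = 1.0 / np.sqrt(np.diag(fixed))
    fixed = fixed * np.outer(scale, scale)
    np.fill_diagonal(fixed, 1.0)
    fixed = (fixed + fixed.T) / 2
    return fixed, True


def assemble_prior_covariance(
    risk_block: np.ndarray,
    si_r: float = SI_CORRELATION,
    cross_block_value: float = 0.3,
    floor: float = PD_EIGENVALUE_FLOOR,
) -> np.ndarray:
    """Join the risk and SI correlation blocks into the m x m joint prior.

    The risk and SI factors were calibrated separately, so their
    cross-correlations are free parameters here: every risk-by-SI entry is
    set to ``cross_block_value``.  If the assembled matrix is not positive
    definite it is repaired by eigenvalue clipping (logged).
    """
    risk_block = np.asarray(risk_block, dtype=float)
    k = risk_block.shape[0]
    if risk_block.ndim != 2 or risk_block.shape[0] != risk_block.shape[1]:
        raise ValueError("risk_block must be square")
    if not np.allclose(risk_block, risk_block.T, atol=1e-8):
        raise ValueError("risk_block must be symmetric")
    if not -1 < si_r < 1:
        raise ValueError("si_r must lie strictly inside (-1, 1)")
    if not -1 < cross_block_value < 1:
        raise ValueError("cross_block_value must lie strictly inside (-1, 1)")

    m = k + 2
    R = np.empty((m, m))
    R[:k, :k] = risk_block
    R[k:, k:] = np.array([[1.0, si_r], [si_r, 1.0]])
    R[:k, k:] = cross_block_value
    R[k:, :k] = cross_block_value

    fixed, repaired = nearest_pd_correlation(R, floor=floor)
    if repaired:
        logger.warning(
            "joint prior correlation was not positive definite; repaired by "
            "clipping eigenvalues at %g and rescaling to unit diagonal",
            floor,
        )
        return fixed
    return R


def default_prior_correlation(cross_block_value: float = 0.3) -> np.ndarray:
    """The default joint 14-domain prior correlation matrix."""
    return assemble_prior_covariance(
        RISK_DOMAIN_CORRELATIONS, SI_CORRELATION, cross_block_value
    )


def default_domains() -> list[DomainSpec]:
    return [
        DomainSpec(i, name, role)
        for i, (name, role) in enumerate(zip(DEFAULT_DOMAIN_NAMES, DEFAULT_DOMAIN_ROLES))
    ]


# ---------------------------------------------------------------------------
# Synthetic bank generation
# ---------------------------------------------------------------------------

@dataclass
class BankConfig:
    """Shape and sampling ranges for synthetic bank generation.

    Defaults reproduce the published bank shape: 189 risk items whose
    strongest loadings spread over 12 risk domains, plus 9 passive and 9
    active suicidal-ideation items.  Primary discriminations are drawn
    log-uniform on [0.8, 2.5]; cross-loadings appear with probability
    ``cross_loading_prob`` and magnitude uniform on [0.3, 0.8].  Item
    locations are uniform on [-1, 2], so the bank is most informative from
    average to high severity.
    """

    domain_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PRIMARY_COUNTS)
    )
    domain_roles: Mapping[str, str] | None = None
    cross_loading_prob: float = 0.15
    a_primary_range: tuple[float, float] = (0.8, 2.5)
    a_cross_range: tuple[float, float] = (0.3, 0.8)
    location_range: tuple[float, float] = (-1.0, 2.0)
    threshold_spread: float = 0.7
    si_r: float = SI_CORRELATION
    cross_block_value: float = 0.3

    def roles(self) -> dict[str, str]:
        if self.domain_roles is not None:
            return dict(self.domain_roles)
        defaults = dict(zip(DEFAULT_DOMAIN_NAMES, DEFAULT_DOMAIN_ROLES))
        return {name: defaults.get(name, "risk") for name in self.domain_counts}


def make_synthetic_bank(
    config: BankConfig | None = None, seed: int = 0
) -> ItemBank:
    """Generate a validated synthetic bank, deterministic given ``seed``."""
    config = config or BankConfig()
    counts = dict(config.domain_counts)
    for name, n in counts.items():
        if n < 1:
            raise ValueError(f"domain {name!r} must have at least 1 item, got {n}")

    names = list(counts)
    roles = config.roles()
    domains = [DomainSpec(i, name, roles[name]) for i, name in enumerate(names)]
    m = len(domains)

    rng = np.random.default_rng(seed)
    lo, hi = config.a_primary_range
    clo, chi = config.a_cross_range
    loc_lo, loc_hi = config.location_range

    items: list[ItemParameters] = []
    for dom in domains:
        for j in range(counts[dom.name]):
            a = np.zeros(m)
            a_primary = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            a[dom.domain_id] = a_primary
            # sparse cross-loadings, never exceeding the primary loading
            for g in range(m):
                if g != dom.domain_id and rng.random() < config.cross_loading_prob:
                    a[g] = min(float(rng.uniform(clo, chi)), 0.95 * a_primary)
            loc = rng.uniform(loc_lo, loc_hi)
            b = np.sort(rng.normal(loc, config.threshold_spread, size=N_THRESHOLDS))
            b += np.arange(N_THRESHOLDS) * 0.15  # enforce strictly ordered boundaries
            d = -a_primary * b
            items.append(
                ItemParameters(
                    item_id=f"{dom.name}_{j + 1:03d}",
                    prompt=f"synthetic {dom.name} item {j + 1}",
                    a=a,
                    d=d,
                    primary_domain=dom.domain_id,
                )
            )

    if m == 14 and names == list(DEFAULT_DOMAIN_NAMES):
        prior = assemble_prior_covariance(
            RISK_DOMAIN_CORRELATIONS, config.si_r, config.cross_block_value
        )
    else:
        # generic fallback: exchangeable correlation within the roster
        prior = np.full((m, m), 0.4)
        np.fill_diagonal(prior, 1.0)
        prior, _ = nearest_pd_correlation(prior)

    return _require_valid(ItemBank(items=items, domains=domains, prior_correlation=prior))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
# CSV interchange: one row per item with columns
#   item_id, prompt, a_0..a_{m-1}, d_1..d_4, primary_domain
# accompanied by <stem>.prior.csv holding the m x m prior correlation with a
# header row of domain names (the role is appended as "name:role").
# JSON mirrors everything in a single document.

def _prior_path(path: Path) -> Path:
    return path.with_suffix(".prior.csv")


def save_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    m = bank.n_domains
    if fmt == "json":
        doc = {
            "domains": [
                {"domain_id": d.domain_id, "name": d.name, "role": d.role}
                for d in bank.domains
            ],
            "prior_correlation": bank.prior_correlation.tolist(),
            "items": [
                {
                    "item_id": it.item_id,
                    "prompt": it.prompt,
                    "a": it.a.tolist(),
                    "d": it.d.tolist(),
                    "primary_domain": it.primary_domain,
                }
                for it in bank.items
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif fmt == "csv":
        header = (
            ["item_id", "prompt"]
            + [f"a_{g}" for g in range(m)]
            + [f"d_{k}" for k in range(1, N_THRESHOLDS + 1)]
            + ["primary_domain"]
        )
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for it in bank.items:
                w.writerow(
                    [it.item_id, it.prompt]
                    + [repr(float(v)) for v in it.a]
                    + [repr(float(v)) for v in it.d]
                    + [it.primary_domain]
                )
        with _prior_path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"{d.name}:{d.role}" for d in bank.domains])
            for row in bank.prior_correlation:
                w.writerow([repr(float(v)) for v in row])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load and validate a bank; raises on parse or invariant failure."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        bank = _load_json(path)
    elif fmt == "csv":
        bank = _load_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _require_valid(bank)


def _load_json(path: Path) -> ItemBank:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise BankParseError(f"{path}: invalid JSON ({e})") from e
    try:
        domains = [
            DomainSpec(int(d["domain_id"]), str(d["name"]), str(d["role"]))
            for d in doc["domains"]
        ]
        items = [
            ItemParameters(
                item_id=str(it["item_id"]),
                prompt=str(it.get("prompt", "")),
                a=np.asarray(it["a"], dtype=float),
                d=np.asarray(it["d"], dtype=float),
                primary_domain=int(it["primary_domain"]),
            )
            for it in doc["items"]
        ]
        prior = np.asarray(doc["prior_correlation"], dtype=float)
    except (KeyError, TypeError, ValueError) as e:
        raise BankParseError(f"{path}: malformed bank document ({e})") from e
    return ItemBank(items=items, domains=domains, prior_correlation=prior)


def _load_csv(path: Path) -> ItemBank:
    prior_file = _prior_path(path)
    if not prior_file.exists():
        raise BankParseError(f"{path}: companion prior file {prior_file} not found")
    with prior_file.open() as fh:
        rows = list(csv.reader(fh))
    header, matrix_rows = rows[0], rows[1:]
    domains = []
    for i, cell in enumerate(header):
        name, _, role = cell.partition(":")
        domains.append(DomainSpec(i, name, role or "risk"))
    m = len(domains)
    try:
        prior = np.array([[float(v) for v in row] for row in matrix_rows])
    except ValueError as e:
        raise BankParseError(f"{prior_file}: non-numeric matrix entry ({e})") from e
    if prior.shape != (m, m):
        raise BankParseError(
            f"{prior_file}: matrix shape {prior.shape} does not match "
            f"{m} header domains"
        )

    with path.open() as fh:
        reader = csv.DictReader(fh)
        expected = (
            {"item_id", "prompt", "primary_domain"}
            | {f"a_{g}" for g in range(m)}
            | {f"d_{k}" for k in range(1, N_THRESHOLDS + 1)}
        )
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            missing = expected - set(reader.fieldnames or [])
            raise BankParseError(f"{path}: missing columns {sorted(missing)}")
        items = []
        for lineno, row in enumerate(reader, start=2):
            try:
                items.append(
                    ItemParameters(
                        item_id=row["item_id"],
                        prompt=row["prompt"],
                        a=np.array([float(row[f"a_{g}"]) for g in range(m)]),
                        d=np.array(
                            [float(row[f"d_{k}"]) for k in range(1, N_THRESHOLDS + 1)]
                        ),
                        primary_domain=int(row["primary_domain"]),
                    )
                )
            except (TypeError, ValueError) as e:
                raise BankParseError(f"{path}: row {lineno}: {e}") from e
    return ItemBank(items=items, domains=domains, prior_correlation=prior)
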