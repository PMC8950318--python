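"""Stable-isotope labelling arithmetic for 13C / 15N tracing experiments.

The labelling design is a 50:50 substrate mix of unlabelled metabolite and
[1,2-13C2]glucose (or [15N2]glutamine), so even complete transfer of tracer
atoms leaves product enrichments well below 1.  This module implements the
chain from measured isotopologue abundances to biological conclusions:

* natural-abundance correction of measured isotopologue vectors
  (binomial convolution model, solved by non-negative least squares);
* mean isotopic enrichment E = sum(i * m_i) / n;
* the theoretical maximum enrichment E_max a product can reach under a
  tracer design and an atom-transfer model, e.g. 16.5% for extracellular
  lactate from [1,2-13C2]glucose at 50% tracer and 99% purity;
* fractional contribution c = E / E_max of the tracer substrate to a
  product pool, optionally corrected for pool material already present
  before labelling began;
* the pentose-phosphate split ratio from lactate M1/M2 under
  [1,2-13C2]glucose (oxidative PPP decarboxylates C1, turning would-be M2
  lactate into M1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .errors import ValidationError

#: Natural abundance of the heavy isotope, by element.
NATURAL_ABUNDANCE = {"C": 0.0107, "N": 0.00364}


@dataclass(frozen=True)
class TracerDesign:
    """A labelled-substrate feeding design.

    element: traced element, 'C' or 'N'.
    tracer_fraction: fraction of the substrate pool that is tracer (0.5 for
        the 50:50 unlabelled:labelled media mix).
    purity: isotopic purity of the nominally labelled positions.
    labeled_positions: number of labelled atoms per tracer molecule.
    substrate_atoms: traced-element atom count of the substrate.
    natural_abundance: heavy-isotope natural abundance; defaults by element.
    """

    element: str
    tracer_fraction: float = 0.5
    purity: float = 0.99
    labeled_positions: int = 2
    substrate_atoms: int = 6
    natural_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.element not in NATURAL_ABUNDANCE:
            raise ValidationError(f"unknown element {self.element!r}")
        if self.natural_abundance is None:
            object.__setattr__(
                self, "natural_abundance", NATURAL_ABUNDANCE[self.element]
            )
        for name in ("tracer_fraction", "purity", "natural_abundance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.labeled_positions > self.substrate_atoms:
            raise ValidationError("labeled_positions exceeds substrate_atoms")


@dataclass(frozen=True)
class AtomTransferModel:
    """Expected tracer-derived label transfer into one product molecule.

    ``expected_labeled_atoms`` is the mean number of heavy atoms a product
    molecule carries when the substrate pool is 100% pure tracer, averaged
    over the biochemical routes from substrate to product.
    ``default_apply_purity`` records whether the matching literature value
    folds tracer purity into the maximum.
    """

    name: str
    product_atoms: int
    expected_labeled_atoms: float
    default_apply_purity: bool = True

    def __post_init__(self) -> None:
        if self.product_atoms < 1:
            raise ValidationError("product_atoms must be >= 1")
        if not 0 <= self.expected_labeled_atoms <= self.product_atoms:
            raise ValidationError("expected_labeled_atoms outside [0, product_atoms]")


#: Glycolysis splits [1,2-13C2]glucose into one M2 triose (C1-C3) and one M0
#: triose (C4-C6): a lactate from tracer glucose carries on average 1 label.
LACTATE_FROM_GLUCOSE = AtomTransferModel(
    name="lactate_from_[1,2-13C2]glucose",
    product_atoms=3,
    expected_labeled_atoms=1.0,
    default_apply_purity=True,
)

#: At complete TCA turnover every glutamate carbon equilibrates with the
#: acetyl-CoA carbon enrichment.  Acetyl-CoA from pure tracer glucose is 50%
#: M2 / 50% M0 (one labelled and one unlabelled triose per glucose), i.e.
#: 0.5 heavy atoms per carbon, so glutamate carries 5 x 0.5 = 2.5 expected
#: labels.  The matching literature maximum (25% at a 50:50 mix) does not
#: fold in purity.
GLUTAMATE_FROM_GLUCOSE = AtomTransferModel(
    name="glutamate_from_[1,2-13C2]glucose_complete_turnover",
    product_atoms=5,
    expected_labeled_atoms=2.5,
    default_apply_purity=False,
)

ATOM_TRANSFER_MODELS = {
    m.name: m for m in (LACTATE_FROM_GLUCOSE, GLUTAMATE_FROM_GLUCOSE)
}

#: The study's feeding designs.
GLUCOSE_12C2_TRACER = TracerDesign(
    element="C", tracer_fraction=0.5, purity=0.99, labeled_positions=2, substrate_atoms=6
)
GLUTAMINE_15N2_TRACER = TracerDesign(
    element="N", tracer_fraction=0.5, purity=0.99, labeled_positions=2, substrate_atoms=2
)


@dataclass
class IsotopologueVector:
    """Fractional isotopologue abundances m0..mn of one metabolite."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 1 or self.m.size < 2:
            raise ValidationError("isotopologue vector needs entries m0..mn, n >= 1")
        if (self.m < -1e-12).any():
            raise ValidationError("isotopologue fractions must be non-negative")
        total = self.m.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"isotopologue fractions sum to {total}, not 1")

    @property
    def n(self) -> int:
        return self.m.size - 1


@dataclass
class EnrichmentResult:
    """Summary of one metabolite's labelling state."""

    mean_enrichment: float
    theoretical_max: float
    contribution: float
    preexisting_fraction: float = field(default=0.0)


def correction_matrix(n: int, a: float) -> np.ndarray:
    """Natural-abundance convolution matrix for an n-atom metabolite.

    Entry (i, j) is the probability that a molecule with j tracer-derived
    labels is measured as M_i because i - j of its n - j unlabelled
    positions carry a naturally occurring heavy atom:
    C(n-j, i-j) * a^(i-j) * (1-a)^(n-i).  Columns sum to 1.
    """
    if n < 1:
        raise ValidationError("atom count must be >= 1")
    if not 0 <= a < 1:
        raise ValidationError("natural abundance must lie in [0, 1)")
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    with np.errstate(invalid="ignore"):
        mat = scipy.stats.binom.pmf(i - j, n - j, a)
    return np.where(i >= j, mat, 0.0)


def correct_natural_abundance(
    measured: IsotopologueVector, a: float, residual_tol: float = 1e-6
) -> IsotopologueVector:
    """Deconvolve natural abundance out of a measured isotopologue vector.

    Solves ``correction_matrix @ x = measured`` under x >= 0 by non-negative
    least squares (plain inversion can go negative on noisy data) and
    renormalises x to sum 1.  A residual above ``residual_tol`` triggers a
    warning naming the residual.
    """
    mat = correction_matrix(measured.n, a)
    x, residual = scipy.optimize.nnls(mat, measured.m)
    if residual > residual_tol:
        warnings.warn(
            f"natural-abundance correction residual {residual:.3g} exceeds "
            f"{residual_tol:g}; measured vector may be inconsistent"
        )
    total = x.sum()
    if total <= 0:
        raise ValidationError("correction produced an all-zero vector")
    return IsotopologueVector(x / total)


def mean_enrichment(v: IsotopologueVector) -> float:
    """Label-count-weighted fraction of heavy atoms: E = sum(i * m_i) / n."""
    i = np.arange(v.n + 1)
    return float((i * v.m).sum() / v.n)


def theoretical_max_enrichment(
    model: AtomTransferModel,
    design: TracerDesign,
    apply_purity: bool | None = None,
) -> float:
    """Maximum mean enrichment a product can reach under the design.

    E_max = tracer_fraction * (purity if applied) * expected_labeled_atoms
    / product_atoms.  Whether purity is folded in defaults to the model's
    convention (literature values differ on this).
    """
    if apply_purity is None:
        apply_purity = model.default_apply_purity
    purity = design.purity if apply_purity else 1.0
    return (
        design.tracer_fraction
        * purity
        * model.expected_labeled_atoms
        / model.product_atoms
    )


def fractional_contribution(e_obs: float, e_max: float) -> float:
    """Fraction of a product pool's atoms that came from the tracer substrate."""
    if e_max <= 0:
        raise ValidationError("theoretical maximum enrichment must be positive")
    c = e_obs / e_max
    if c > 1:
        warnings.warn(
            f"observed enrichment {e_obs:.4g} exceeds the theoretical maximum "
            f"{e_max:.4g}; contribution clipped to 1"
        )
    return float(min(max(c, 0.0), 1.0))


def contribution_with_preexisting_pool(
    e_obs: float, phi: float, e_max: float
) -> float:
    """Contribution corrected for pool material present before labelling.

    A fraction ``phi`` of the measured pool predates the tracer and dilutes
    the observed enrichment, so the newly made material is enriched at
    E_obs / (1 - phi) and c = (E_obs / (1 - phi)) / E_max.
    """
    if not 0 <= phi < 1:
        raise ValidationError("preexisting fraction must lie in [0, 1)")
    return fractional_contribution(e_obs / (1.0 - phi), e_max)


def ppp_fraction(m1: float, m2: float, estimator: str = "lee") -> float:
    """Pentose-phosphate split ratio from lactate M1/M2 under [1,2-13C2]glucose.

    Oxidative PPP removes the labelled C1 as CO2, so glucose routed through
    the PPP yields M1 lactate where direct glycolysis yields M2.  The 'lee'
    estimator (default, pentose-cycle literature) is
    PC = (m1/m2) / (3 + m1/m2); 'simple' is the naive ratio m1 / (m1 + m2).
    """
    if m1 < 0 or m2 < 0:
        raise ValidationError("isotopologue fractions must be non-negative")
    if m1 == 0 and m2 == 0:
        raise ValidationError("m1 and m2 cannot both be zero")
    if estimator == "lee":
        if m2 == 0:
            raise ValidationError("'lee' estimator undefined for m2 = 0")
        ratio = m1 / m2
        return float(ratio / (3.0 + ratio))
    if estimator == "simple":
        return float(m1 / (m1 + m2))
    raise ValidationError(f"unknown PPP estimator {estimator!r}")


def ppp_fraction_all(m1: float, m2: float) -> dict[str, float]:
    """Both PPP estimators side by side."""
    return {
        "lee": ppp_fraction(m1, m2, "lee"),
        "simple": ppp_fraction(m1, m2, "simple"),
    }


def enrichment_result(
    v: IsotopologueVector,
    model: AtomTransferModel,
    design: TracerDesign,
    phi: float = 0.0,
    apply_purity: bool | None = None,
    correct: bool = True,
) -> EnrichmentResult:
    """One-stop summary: correct, enrich, and express as a contribution."""
    if correct:
        v = correct_natural_abundance(v, design.natural_abundance)
    e = mean_enrichment(v)
    e_max = theoretical_max_enrichment(model, design, apply_purity)
    if phi > 0:
        c = contribution_with_preexisting_pool(e, phi, e_max)
    else:
        c = fractional_contribution(e, e_max)
    return EnrichmentResult(
        mean_enrichment=e,
        theoretical_max=e_max,
        contribution=c,
        preexisting_fraction=phi,
    )
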