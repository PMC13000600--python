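"""Drug-likeness filters at the fragment level: Rule of Three and QED.

The Rule of Three keeps fragment-sized, lead-like pieces: MW < 300 Da,
HBA <= 3, HBD <= 3, logP <= 3, plus the customary extensions NROT <= 3 and
PSA <= 60 A^2.  The number of allowed rule mismatches is configurable
(default 0: all six criteria must hold).

QED (quantitative estimate of drug-likeness) maps eight molecular properties
(MW, logP, HBA, HBD, PSA, NROT, aromatic rings, structural alerts) through
asymmetric double-sigmoid desirability functions d_i and combines them as a
weighted geometric mean

    QED = exp( sum_i w_i ln d_i / sum_i w_i )  in (0, 1].

The default acceptance threshold, 0.464, is the lower 25% quantile of QED
over fragments cut from approved/clinical kinase inhibitors; the same
derivation is available for any user-supplied reference set.

All descriptors are computed on the dummy-free fragment, so attachment
points never shift a property value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

from .core import Fragment, FragmentLibrary, strip_attachment_points

#: default QED threshold: lower-quartile QED of fragments from approved and
#: clinical-trial kinase inhibitors
DEFAULT_QED_THRESHOLD = 0.464

_QED_WEIGHTS = {
    "mean": QED.WEIGHT_MEAN,
    "max": QED.WEIGHT_MAX,
    "unit": QED.WEIGHT_NONE,
}
_QED_PROPS = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")


@dataclass(frozen=True)
class Ro3Config:
    """Rule-of-Three thresholds and the allowed number of mismatches.

    ``hba_definition`` selects how acceptors/donors are counted: ``'lipinski'``
    (N+O / NH+OH counts) or ``'topological'`` (pharmacophore-typed acceptor
    and donor definitions).  Ro3 counts are definition-sensitive, so the
    choice is explicit.
    """

    mw_max: float = 300.0  # strict: MW must be < mw_max
    hba_max: int = 3
    hbd_max: int = 3
    logp_max: float = 3.0
    nrot_max: int = 3
    psa_max: float = 60.0
    max_mismatches: int = 0
    hba_definition: str = "lipinski"

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches <= 6:
            raise ValueError("max_mismatches must be within [0, 6]")
        if self.hba_definition not in ("lipinski", "topological"):
            raise ValueError("hba_definition must be 'lipinski' or 'topological'")


@dataclass(frozen=True)
class Ro3Profile:
    """The six Rule-of-Three descriptors of one fragment plus its violation count."""

    mw: float
    hba: int
    hbd: int
    logp: float
    nrot: int
    psa: float
    violations: int


def ro3_profile(fragment: Fragment | Chem.Mol, config: Ro3Config = Ro3Config()) -> Ro3Profile:
    """Compute the Rule-of-Three descriptor profile of a dummy-free fragment."""
    mol = strip_attachment_points(fragment)
    if config.hba_definition == "lipinski":
        hba, hbd = Lipinski.NOCount(mol), Lipinski.NHOHCount(mol)
    else:
        hba, hbd = Lipinski.NumHAcceptors(mol), Lipinski.NumHDonors(mol)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    nrot = Lipinski.NumRotatableBonds(mol)
    psa = Descriptors.TPSA(mol)
    violations = sum(
        [
            mw >= config.mw_max,  # "less than 300 Da"
            hba > config.hba_max,
            hbd > config.hbd_max,
            logp > config.logp_max,
            nrot > config.nrot_max,
            psa > config.psa_max,
        ]
    )
    return Ro3Profile(mw=mw, hba=hba, hbd=hbd, logp=logp, nrot=nrot, psa=psa, violations=violations)


@dataclass(frozen=True)
class QedResult:
    """QED score with its per-property desirabilities and weights."""

    score: float
    desirabilities: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)


def qed(mol_or_fragment: Fragment | Chem.Mol, weights: str = "mean") -> QedResult:
    """QED of a molecule as the weighted geometric mean of eight desirabilities.

    ``weights`` selects the published weight set: ``'mean'`` (default),
    ``'max'``, or ``'unit'`` (all ones).
    """
    mol = strip_attachment_points(mol_or_fragment)
    try:
        w = _QED_WEIGHTS[weights]
    except KeyError:
        raise ValueError(f"unknown QED weight set {weights!r}") from None
    props = QED.properties(mol)
    desirabilities = {
        name: QED.ads(getattr(props, name), QED.adsParameters[name]) for name in _QED_PROPS
    }
    w_map = {name: getattr(w, name) for name in _QED_PROPS}
    log_d = np.array([np.log(max(desirabilities[n], 1e-300)) for n in _QED_PROPS])
    w_arr = np.array([w_map[n] for n in _QED_PROPS])
    score = float(np.exp(np.sum(w_arr * log_d) / np.sum(w_arr)))
    return QedResult(score=score, desirabilities=desirabilities, weights=w_map)


def derive_qed_threshold(
    reference_fragments: Iterable[Fragment | Chem.Mol],
    quantile: float = 0.25,
    weights: str = "mean",
) -> float:
    """Quantile of dummy-free QED scores over a reference fragment set.

    Uses the linear-interpolation quantile definition.  The pipeline default
    threshold (0.464) is this statistic at the lower quartile over fragments
    of approved/clinical kinase inhibitors.
    """
    scores = [qed(f, weights=weights).score for f in reference_fragments]
    if len(scores) == 0:
        raise ValueError("reference fragment set is empty")
    if len(scores) < 4:
        raise ValueError("need at least 4 reference fragments for a stable quantile")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    return float(np.quantile(scores, quantile, method="linear"))


def filter_properties(
    library: FragmentLibrary,
    ro3_config: Ro3Config = Ro3Config(),
    qed_threshold: float = DEFAULT_QED_THRESHOLD,
    qed_weights: str = "mean",
) -> pd.DataFrame:
    """Per-fragment pass flags: column ``ro3`` and column ``qed``.

    A fragment fails Ro3 iff its violation count exceeds
    ``ro3_config.max_mismatches`` and fails QED iff its score is below
    ``qed_threshold``.
    """
    fragments = library.fragments()
    ro3_pass, qed_pass = [], []
    for f in fragments:
        profile = ro3_profile(f, ro3_config)
        ro3_pass.append(profile.violations <= ro3_config.max_mismatches)
        qed_pass.append(qed(f, weights=qed_weights).score >= qed_threshold)
    return pd.DataFrame({"ro3": ro3_pass, "qed": qed_pass}, index=range(len(fragments)))


def ro5_veber_table(mols: Sequence[Chem.Mol]) -> pd.DataFrame:
    """Lipinski Rule-of-Five and Veber descriptors/pass flags per molecule.

    Ro5: MW <= 500, logP <= 5, HBD <= 5, HBA <= 10 (Lipinski counts).
    Veber: NROT <= 10, PSA <= 140 A^2.
    """
    rows = []
    for mol in mols:
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        hbd = Lipinski.NHOHCount(mol)
        hba = Lipinski.NOCount(mol)
        nrot = Lipinski.NumRotatableBonds(mol)
        psa = Descriptors.TPSA(mol)
        rows.append(
            {
                "mw": mw,
                "logp": logp,
                "hbd": hbd,
                "hba": hba,
                "nrot": nrot,
                "psa": psa,
                "ro5_pass": mw <= 500 and logp <= 5 and hbd <= 5 and hba <= 10,
                "veber_pass": nrot <= 10 and psa <= 140,
            }
        )
    return pd.DataFrame(rows)
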