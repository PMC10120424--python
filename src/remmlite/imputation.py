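"""Constant-policy imputation of missing feature values.

Three policies are supported, chosen per feature:

* ``zero`` — missing means "signal too low to measure"; appropriate for
  epigenetic and regulatory-element tracks;
* ``genome-mean`` — the average of the defined values of that feature;
  appropriate for sequence-composition and conservation features, where a
  missing annotation does not imply absence of signal. The mean is a
  training-time statistic and is reused unchanged at scoring time;
* ``one`` — for P-value-like features, where "no test" is best encoded as
  the null P value of 1.

No model-based imputation (kNN, MICE, ...) is attempted: decision-tree
ensembles tolerate constant fill-ins well and the constant policies keep
scoring deterministic and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import IMPUTATION_POLICIES, FeatureMatrix, FeatureMeta

__all__ = ["ImputationPolicy", "policy_from_metadata", "fit_imputer", "impute"]


@dataclass
class ImputationPolicy:
    """Per-feature policy plus, after fitting, the stored genome-mean values."""

    policies: dict[str, str]
    means_: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def __post_init__(self) -> None:
        for name, pol in self.policies.items():
            if pol not in IMPUTATION_POLICIES:
                raise ValueError(
                    f"unknown policy {pol!r} for feature {name!r}; "
                    f"expected one of {IMPUTATION_POLICIES}"
                )

    def fill_value(self, feature: str) -> float:
        pol = self.policies[feature]
        if pol == "zero":
            return 0.0
        if pol == "one":
            return 1.0
        if not self.fitted:
            raise RuntimeError("genome-mean policy requires a fitted imputer")
        return self.means_[feature]


def policy_from_metadata(metadata: Sequence[FeatureMeta]) -> ImputationPolicy:
    """Policy declared in the feature metadata (one policy per feature)."""
    return ImputationPolicy({m.name: m.imputation for m in metadata})


def fit_imputer(matrix: FeatureMatrix, policy: ImputationPolicy) -> ImputationPolicy:
    """Compute the per-feature means required by ``genome-mean`` policies.

    The stored mean of a feature is the arithmetic mean over its non-missing
    entries only (the available stand-in for the genome-wide average of the
    annotation). A genome-mean feature with no defined value is an error —
    there is no silent fallback.
    """
    means: dict[str, float] = {}
    for j, name in enumerate(matrix.feature_names):
        if name not in policy.policies:
            raise KeyError(f"feature {name!r} has no declared imputation policy")
        if policy.policies[name] != "genome-mean":
            continue
        defined = matrix.values[~matrix.mask[:, j], j]
        if defined.size == 0:
            raise ValueError(
                f"feature {name!r} is entirely missing; cannot fit genome-mean"
            )
        means[name] = float(defined.mean())
    return ImputationPolicy(dict(policy.policies), means_=means, fitted=True)


def impute(matrix: FeatureMatrix, policy: ImputationPolicy) -> FeatureMatrix:
    """Replace every missing cell per its feature's policy.

    Non-missing cells are never modified; the returned matrix has an
    all-false mask. Idempotent: imputing an imputed matrix is the identity.
    """
    if not policy.fitted:
        raise RuntimeError("imputer must be fitted before use (fit_imputer)")
    values = matrix.values.copy()
    for j, name in enumerate(matrix.feature_names):
        if name not in policy.policies:
            raise KeyError(f"feature {name!r} has no declared imputation policy")
        miss = matrix.mask[:, j]
        if miss.any():
            values[miss, j] = policy.fill_value(name)
    return FeatureMatrix(values, np.zeros_like(matrix.mask), matrix.metadata)
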