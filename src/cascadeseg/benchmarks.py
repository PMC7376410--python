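"""Published evaluation indices of the cascade and its single-model baselines.

These are the reported DSC / sensitivity / specificity operating points of
the DCNN-F-SVM cascade versus a stand-alone RBF-SVM and a stand-alone CNN,
on the BraTS18 benchmark (three-fold cross-validation) and on a 26-patient
clinical cohort.  They are inputs for computing the relative improvement the
cascade delivers over each baseline — the quantity this package's
:func:`cascadeseg.metrics.relative_improvement` reports — not values this
package claims to reproduce from raw data (the underlying datasets are
gated/private).
"""

from __future__ import annotations

from typing import Dict

from .metrics import relative_improvement

__all__ = ["BRATS18_INDICES", "CLINICAL_INDICES", "INDEX_NAMES", "improvement_over_baselines"]

INDEX_NAMES = ("dsc", "sensitivity", "specificity")

#: BraTS18 three-fold cross-validation operating points per method.
BRATS18_INDICES: Dict[str, Dict[str, float]] = {
    "SVM": {"dsc": 0.8268, "sensitivity": 0.8306, "specificity": 0.9845},
    "CNN": {"dsc": 0.8556, "sensitivity": 0.8876, "specificity": 0.9962},
    "DCNN-F-SVM": {"dsc": 0.8958, "sensitivity": 0.9110, "specificity": 0.9982},
}

#: 26-patient clinical cohort means per method.
CLINICAL_INDICES: Dict[str, Dict[str, float]] = {
    "SVM": {"dsc": 0.8705, "sensitivity": 0.9001, "specificity": 0.9586},
    "CNN": {"dsc": 0.8869, "sensitivity": 0.9152, "specificity": 0.9657},
    "DCNN-F-SVM": {"dsc": 0.9010, "sensitivity": 0.9236, "specificity": 0.9889},
}


def improvement_over_baselines(indices: Dict[str, Dict[str, float]],
                               method: str = "DCNN-F-SVM") -> Dict[str, Dict[str, float]]:
    """Relative percent improvement of ``method`` over every other method.

    Returns {baseline: {index: percent}} with each percent computed as
    100·(method − baseline)/baseline, rounded to one decimal place.
    """
    out: Dict[str, Dict[str, float]] = {}
    for baseline, vals in indices.items():
        if baseline == method:
            continue
        out[baseline] = {
            name: relative_improvement(indices[method][name], vals[name])
            for name in INDEX_NAMES
        }
    return out
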