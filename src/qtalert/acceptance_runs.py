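"""Canonical evaluation runs used by the validation suite and scripts.

Groups the study-condition runs — the permutation-label negative
control at the reference cohort sizes (144 positive / 95 negative) —
behind one function so tests and reporting scripts execute exactly the
same computation.
"""

from __future__ import annotations

from .sar import CVConfig, CVSummary, Hyperparams, permutation_control
from .synthetic import SignalMatrixSpec, generate_signal_matrix


def permutation_reference_run(
    seed: int, n_iterations: int = 100, n_features: int = 50
) -> CVSummary:
    """Permutation control at the reference class sizes.

    A 239-sample noise feature matrix (144 positive / 95 negative,
    ``n_features`` independent standard-normal columns) is evaluated by
    the RBF-SVM under repeated stratified 5-fold CV with labels
    re-permuted each iteration.
    """
    matrix, _ = generate_signal_matrix(
        SignalMatrixSpec(
            n_pos=144, n_neg=95, n_informative=0, effect_size=0.0,
            n_noise=n_features, seed=seed,
        )
    )
    config = CVConfig(n_folds=5, n_iterations=n_iterations, seed=seed + 1)
    return permutation_control(matrix, config, Hyperparams(family="svm-rbf"))
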