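"""Package-wide defaults and logging.

Every tunable that the pipeline consumes lives here so that no experiment
silently hard-codes a value: preprocessing thresholds, local-learner
hyperparameters, and the federation schedule all reference these constants
and record the value actually used in their run manifests.
"""

from __future__ import annotations

import logging

# --- preprocessing -------------------------------------------------------
#: quantile of the extra-trees importance distribution below which a
#: feature is dropped during selection.
DEFAULT_IMPORTANCE_QUANTILE = 0.5
#: squared-correlation cap for redundancy pruning; of any feature pair with
#: r^2 above this the lower-importance member is dropped.
DEFAULT_CORRELATION_CAP = 0.36
#: floor applied to per-feature standard deviations so constant columns
#: standardize to zero instead of dividing by zero.
SD_FLOOR = 1e-12

# --- local learners ------------------------------------------------------
DEFAULT_LEARNING_RATE = 0.1
DEFAULT_BATCH_SIZE = 32
DEFAULT_L2 = 1e-4
#: hidden-layer widths of the MLP local learner.
DEFAULT_HIDDEN = (32,)
#: boosted-forest schedule: trees grown per local fit, tree depth, shrinkage.
DEFAULT_TREES_PER_ROUND = 10
DEFAULT_TREE_MAX_DEPTH = 3
DEFAULT_TREE_SHRINKAGE = 0.3

# --- federation ----------------------------------------------------------
#: communication rounds per federated training run.
DEFAULT_ROUNDS = 5
#: local passes over each client shard per round.
DEFAULT_LOCAL_EPOCHS = 1
#: retries for random split strategies that draw a single-class shard.
MAX_SPLIT_RETRIES = 100

# --- evaluation ----------------------------------------------------------
#: decision threshold for all thresholded metrics.
DEFAULT_THRESHOLD = 0.5
#: cross-validation folds.
DEFAULT_K = 6
#: probability clip for log loss.
LOG_LOSS_EPS = 1e-15

logger = logging.getLogger("fedsilo")


def configure_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Attach a plain-text handler at run/round/fold granularity."""
    handler: logging.Handler
    handler = logging.FileHandler(logfile) if logfile else logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
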