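"""On-the-fly database reduction to the subsystems of the predicted genera."""

from __future__ import annotations

import logging
import warnings
from collections import OrderedDict

from subsysfocus.presence import PresenceMatrix
from subsysfocus.subsystem_db import ClusteredDatabase
from subsysfocus.taxonomy import TaxonomicProfile

logger = logging.getLogger(__name__)


def select_subsystems(profile: TaxonomicProfile, matrix: PresenceMatrix) -> set[str]:
    """Union of presence-matrix rows over the reported genera.

    Falls back to every subsystem (with a prominent warning) when nothing is
    selected — annotating against an empty database is strictly worse than
    slow-but-correct.
    """
    selected: set[str] = set()
    for genus in profile.reported_genera:
        if genus not in matrix.genera:
            warnings.warn(
                f"genus {genus!r} predicted in the sample is absent from the "
                "presence matrix; skipped",
                stacklevel=2,
            )
            continue
        selected |= matrix.row(genus)
    if not selected:
        warnings.warn(
            "database reduction selected ZERO subsystems; falling back to the "
            "FULL subsystem set",
            stacklevel=2,
        )
        return set(matrix.subsystems)
    return selected


def reduce_database(db: ClusteredDatabase, keep: set[str]) -> ClusteredDatabase:
    """A view of ``db`` restricted to the subsystems in ``keep``.

    Cluster objects are shared, not copied, so repeated reductions with
    different profiles are cheap. Unknown labels are ignored with a warning.
    """
    unknown = keep - set(db.clusters)
    if unknown:
        warnings.warn(
            f"{len(unknown)} requested subsystem(s) not in the database "
            f"(e.g. {sorted(unknown)[:3]}); ignored",
            stacklevel=2,
        )
    clusters = OrderedDict(
        (level3, cls) for level3, cls in db.clusters.items() if level3 in keep
    )
    if not clusters:
        raise ValueError("reduction produced an empty database")
    reduced = ClusteredDatabase(identity_cutoff=db.identity_cutoff, clusters=clusters)
    logger.info(
        "reduced database: %d/%d subsystems retained (%.1f%%), %d/%d representatives",
        len(clusters), len(db.clusters),
        100.0 * len(clusters) / len(db.clusters),
        reduced.n_representatives, db.n_representatives,
    )
    return reduced
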