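"""Exception and warning types raised across the seedhull pipeline."""


class SeedHullError(Exception):
    """Base class for all seedhull errors."""


# --- calibration ---------------------------------------------------------
class NoBoardFound(SeedHullError):
    """Too few checkerboard saddle points survived filtering."""


class AmbiguousOrdering(SeedHullError):
    """Grid topology of detected corners could not be recovered."""


class DegenerateConfiguration(SeedHullError):
    """Too few / collinear correspondences for pose estimation."""


class DegenerateTrajectory(SeedHullError):
    """Corner trajectory is collinear or has fewer than 3 points."""


class InsufficientCenters(SeedHullError):
    """Fewer than 2 distinct circle centers for axis fitting."""


class InvalidIntrinsics(SeedHullError):
    """Non-positive focal scale factors."""


class IllConditionedAxisWarning(UserWarning):
    """Circle centers nearly isotropic; axis direction poorly determined."""


# --- silhouette ----------------------------------------------------------
class DegenerateHistogram(SeedHullError):
    """Image is constant; no threshold separates two classes."""


class EmptyMask(SeedHullError):
    """Binary mask has no foreground."""


class NoIntersectionWarning(UserWarning):
    """No nozzle/seed intersection row found; mask returned unchanged."""


# --- visual hull ---------------------------------------------------------
class EmptyHull(SeedHullError):
    """No voxel survived carving / grid has no occupancy."""


class EmptySilhouetteWarning(UserWarning):
    """A silhouette is empty; the carved hull will be empty."""


# --- traits --------------------------------------------------------------
class InsufficientSlices(SeedHullError):
    """Fewer than 2 cross-section slices for volume integration."""


class DegenerateOutline(SeedHullError):
    """Outline polygon has fewer than 3 vertices or zero perimeter."""


# --- variation statistics ------------------------------------------------
class ZeroMean(SeedHullError):
    """Mean is zero; coefficient of variation undefined."""


class TooFewValues(SeedHullError):
    """Sample too small for the requested statistic."""


class InsufficientReplication(SeedHullError):
    """Design lacks groups/varieties/replicates for nested ANOVA."""


class ZeroParentMean(SeedHullError):
    """Summed parental mean is zero; GVF undefined."""


class MissingParent(SeedHullError):
    """A parent label is absent from the trait table."""


class DegenerateClustering(SeedHullError):
    """Clustering produced fewer nonempty clusters than requested."""


# --- synthetic fixtures --------------------------------------------------
class InvalidSpec(SeedHullError):
    """Synthetic fixture specification violates its invariants."""


class OutOfFrustum(SeedHullError):
    """Object to render is not (fully) inside the camera frustum."""
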