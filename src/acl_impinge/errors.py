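"""Exception hierarchy for the impingement pipeline."""


class AclImpingeError(Exception):
    """Base class for all package errors."""


class MeshError(AclImpingeError):
    """Invalid mesh data (degenerate faces, bad orientation, I/O problems)."""


class WatertightError(MeshError):
    """Mesh is not a closed 2-manifold; carries the open-edge count."""

    def __init__(self, message: str, open_edges: int = 0):
        super().__init__(message)
        self.open_edges = open_edges


class LandmarkError(AclImpingeError):
    """Missing or inconsistent named landmark points."""


class FrameError(AclImpingeError):
    """Reference frame could not be constructed (collinear/degenerate input)."""


class ProjectionError(AclImpingeError):
    """Surface projection ray missed the mesh (inconsistent frame)."""


class GraftError(AclImpingeError):
    """Invalid virtual-graft geometry."""


class NotchError(AclImpingeError):
    """Intercondylar notch could not be located in the anterior view."""


class InfeasibleParamsError(AclImpingeError):
    """Synthetic-knee parameter combination violates a feasibility constraint."""


class StatsError(AclImpingeError):
    """Statistical test preconditions violated (group sizes, missing pairs)."""
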