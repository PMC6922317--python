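"""Exception hierarchy shared by the holoquant pipelines."""


class HoloquantError(Exception):
    """Base class for all holoquant errors."""


class FormatError(HoloquantError):
    """An input file is not in the expected format (e.g. integer-typed TIFF,
    where the refractive-index meaning of voxel values would be lost)."""


class PhantomSpecError(HoloquantError):
    """A phantom specification is internally inconsistent (e.g. an organelle
    placed outside the cell body)."""


class InstrumentError(HoloquantError):
    """Invalid optical-instrument parameters."""


class InsufficientFeaturesError(HoloquantError):
    """Too few accepted feature matches between a pair of frames."""

    def __init__(self, frame_t, frame_t1, n_found, n_required):
        self.frame_t = frame_t
        self.frame_t1 = frame_t1
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"frame pair ({frame_t}, {frame_t1}): {n_found} accepted matches, "
            f"{n_required} required"
        )


class EstimationError(HoloquantError):
    """Robust model estimation failed (e.g. degenerate correspondences)."""


class ReflectionError(HoloquantError):
    """A homography's linear block has non-positive determinant; no in-plane
    rotation angle is defined."""


class EmptyTraceError(HoloquantError):
    """Every frame pair of a sequence failed; no rotation trace available."""
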