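"""Central table of engine constants.

Every tunable that is not derivable from input data lives here so the CLI
config layer has a single source of defaults.
"""

# --- collider selection -----------------------------------------------------
EIGEN_THRESHOLD = 1.15          # circle vs rectangle decision (eigenvalue ratio)
COARSEN_FACTOR = 1.3            # atom radius inflation when rendering sprites
OUTLINE_SHADE = 0.55            # outline color = fill * OUTLINE_SHADE

# --- lock tool --------------------------------------------------------------
LOCK_BANDWIDTH_NM = 8.0         # mean-shift window for lock clustering
MEANSHIFT_TOL_NM = 0.01         # convergence threshold per iteration
MEANSHIFT_MAX_ITER = 200
HULL_BUFFER_QUAD_SEGS = 4       # arc resolution of dilated lock hulls

# --- fibers / membranes -----------------------------------------------------
SPRING_PRESETS = {"dna": 10, "rna": 0, "membrane": 3, "user": 3}
SPRING_STIFFNESS = 0.5          # projection fraction per solver iteration
LAYER_JUMP_PERIOD = 15          # subunits between layer jumps in auto policy

# --- physics ----------------------------------------------------------------
DT = 1.0
SOLVER_ITERATIONS = 8
POSITION_TOLERANCE_NM = 0.05
DIFFUSION_SCALE = 0.05          # nm^2 per step for a unit-area body
ANGULAR_DIFFUSION = 0.02        # rad std per step for a unit-area body
HINGE_RELAXATION = 0.8          # Jacobi under-relaxation for hinge batches
BROADPHASE_MARGIN_NM = 0.5

# --- scene ops --------------------------------------------------------------
LOCAL_SETTLE_STEPS = 50
LOCAL_SETTLE_RADIUS_DIAMETERS = 3.0

# --- rendering --------------------------------------------------------------
DEPTH_CUE = {0: 0.0, 1: 0.30, 2: 0.60}   # blend fraction toward background
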