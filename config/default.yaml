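# Full default configuration of the litchi grading pipeline.
# Every parameter the source workflow leaves unstated lives here so the
# choices are auditable in one place.  Values mirror PipelineConfig defaults.

# synthetic data ------------------------------------------------------------
n_per_class: 30            # modeling pool: 4 x 30 = 120 samples
n_external_per_class: 20   # external validation: 4 x 20 = 80 samples
gain: 3000.0               # counts per unit reflectance
scene: {}                  # SceneSpec overrides, e.g. {height: 96, texture_std: 0.02}

# spectra -------------------------------------------------------------------
trim_lo_nm: 450.0          # drop noisy bands below 450 nm ...
trim_hi_nm: 850.0          # ... and above 850 nm before modeling
roi_size: 50               # 50 x 50 pixel ROI window
sg_window: 11              # Savitzky-Golay window (bands, odd)
sg_polyorder: 2
prep_mode: both            # baseline | detrend | both

# PLS-DA --------------------------------------------------------------------
calibration_fraction: 0.6  # stratified 60/40 split
max_latent: 10             # LOO-CV search ceiling

# PCA band selection --------------------------------------------------------
n_pc: 7
selection_pc: 3            # loading-extrema source component
max_pixels: 50000
smooth_window: 7
min_prominence_frac: 0.05

# segmentation + texture ----------------------------------------------------
image_source: "band:725"   # gray image for segmentation/GLCM; or "pc:3"
glcm_levels: 64
glcm_distance: 1

# LS-SVM --------------------------------------------------------------------
gamma_grid: [1.0, 10.0, 100.0, 1000.0, 10000.0]
sigma2_grid: [0.1, 1.0, 10.0, 100.0]
cv_folds: 5

# bookkeeping ---------------------------------------------------------------
seed: 42
out_dir: results/pipeline
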