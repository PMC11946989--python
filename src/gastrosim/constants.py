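"""Named physical and protocol constants used as defaults across the package.

Every number that parameterizes the simulated rig lives here so that a
configuration file can override it in one place.  Units are given per
constant; pressures are mmHg, flows mL/s, times s, motor commands PWM
counts (0-255 duty on an 8-bit driver).
"""

# --- Actuation -------------------------------------------------------------
#: Free flow rating of each diaphragm pump, 8 L/min expressed in mL/s.
PUMP_FREE_FLOW_ML_S: float = 8000.0 / 60.0
#: Full-scale PWM duty count of the motor driver.
PWM_MAX: int = 255

# --- Plant -----------------------------------------------------------------
#: Standard atmosphere, mmHg.
ATMOSPHERIC_PRESSURE_MMHG: float = 760.0
#: Adult-stomach-scale resting gas volume of the cavity, mL.
DEFAULT_BASE_VOLUME_ML: float = 1000.0
#: Lowest absolute pressure the suction side may reach, as a fraction of
#: atmospheric; prevents unphysical (negative-absolute-pressure) states.
MIN_ABSOLUTE_FRACTION: float = 0.05

# --- Control ---------------------------------------------------------------
#: Regulation target: median intragastric pressure during diagnostic
#: endoscopy, mmHg gauge.
SETPOINT_MMHG: float = 10.0
#: Aggressive PID gains, engaged for large setpoint error.
AGGRESSIVE_KP, AGGRESSIVE_KI, AGGRESSIVE_KD = 40.0, 10.05, 20.0
#: Conservative PID gains, engaged near the setpoint.
CONSERVATIVE_KP, CONSERVATIVE_KI, CONSERVATIVE_KD = 4.0, 10.2, 40.0
#: |error| above this switches to the aggressive gain set, mmHg.
SWITCH_THRESHOLD_MMHG: float = 2.0
#: |error| at or below this stops both pumps, mmHg (centi-mmHg resolution).
STOP_BAND_MMHG: float = 0.05

# --- Sampling --------------------------------------------------------------
#: Measured mean logging interval of the acquisition chain, s.
SAMPLE_INTERVAL_S: float = 0.0519
#: Measured standard deviation of the logging interval, s.
SAMPLE_JITTER_SD_S: float = 0.0026
#: Long-run (24 h scale) relative-pressure SD of the open-loop sensor, mmHg.
MONITOR_NOISE_SD_MMHG: float = 0.8543
#: Short-term per-sample electronic noise used inside the control loop, mmHg.
LOOP_NOISE_SD_MMHG: float = 0.01

# --- Calibration protocol --------------------------------------------------
#: Suction sweep levels: -100 to -675 mmHg in 25 mmHg increments (24 levels).
CALIBRATION_LEVELS_MMHG: tuple[float, ...] = tuple(
    float(-100 - 25 * k) for k in range(24)
)
#: Settling time allowed after each sweep increment, s.
CALIBRATION_STABILIZE_S: float = 3.0
#: Number of samples averaged immediately before each increment.
CALIBRATION_N_AVG: int = 20

# --- Disturbance protocol --------------------------------------------------
#: Number of cough/belch bursts per spike protocol.
SPIKE_COUNT: int = 10
#: Duration of one external-pump burst, s.
SPIKE_DURATION_S: float = 0.5
#: Monitoring window after each burst before the next one, s.
SPIKE_GAP_S: float = 10.0
#: External-pump burst magnitude, PWM (maximum speed).
SPIKE_MAGNITUDE_PWM: int = 255
#: Respiratory pressure oscillation amplitude, mmHg.
BREATHING_AMPLITUDE_MMHG: float = 2.0
#: Respiratory rate, cycles per minute.
BREATHING_FREQUENCY_CPM: float = 16.0
#: Breathing / mixed protocol duration, s (10 min).
BREATHING_DURATION_S: float = 600.0

# --- Analysis --------------------------------------------------------------
#: Step-response settling band around the setpoint, mmHg.
STEP_RESPONSE_BAND_MMHG: float = 0.5
#: Moving-average window (samples) for the step settling criterion.
STEP_RESPONSE_WINDOW: int = 5
#: Spike-recovery band around the setpoint, mmHg (reach and remain within).
SPIKE_RECOVERY_TOL_MMHG: float = 0.1
#: External-motor-speed threshold for spike segmentation, PWM.
SPIKE_SPEED_THRESHOLD_PWM: float = 50.0
#: Intra-abdominal hypertension grade boundaries (WSACS), mmHg.
IAH_THRESHOLDS_MMHG: tuple[float, float, float, float] = (12.0, 16.0, 21.0, 25.0)

# --- Step-response suite ---------------------------------------------------
#: Number of initial-pressure steps in the response suite.
STEP_SUITE_SIZE: int = 19
#: Lowest / highest initial gauge pressures of the suite, mmHg.
STEP_SUITE_MIN_MMHG: float = 3.8
STEP_SUITE_MAX_MMHG: float = 23.6
#: Uncontrolled stabilization hold before the controller is enabled, s.
STEP_STABILIZE_S: float = 20.0
#: Total per-step protocol duration, s.
STEP_TOTAL_S: float = 60.0
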