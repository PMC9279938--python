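"""Deterministic 2D world, kinematic robot, and the closed control loop.

The robot is a disc on a continuous plane (cm units) with unicycle
kinematics and two single-ray ultrasonic range sensors pointing ±30° off
the heading (a 60° total span).  Readings are the distance along each ray
to the nearest axis-aligned obstacle rectangle, clipped into the sensor's
measurable range [d_min, d_max]; no hit reads d_max.

Every control period (100 ms) the loop senses, advances the spiking
controller for the same interval, decodes the Out-rate into a motion
command, and moves the robot.  A trial terminates on course completion, a
stop command, a timeout — or a collision, in which case the pose freezes
while the network keeps running until it commits to its first turn command
(the decision can come after contact, which is exactly the failure mode of
an untrained controller).

All arithmetic is reflection-exact: mirrored worlds and start poses are
built by negating y-coordinates and headings, so mirrored runs perform
bit-identical computations with the two sensor channels exchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .network import Command, NetworkRuntime, NetworkSpec, decode_action

__all__ = [
    "Pose",
    "Rect",
    "World",
    "SensorRig",
    "MotionParams",
    "TrialLog",
    "sense",
    "robot_step",
    "check_collision",
    "make_scenario",
    "mirror_world",
    "run_closed_loop",
    "SCENARIOS",
]


def _wrap_angle(a: float) -> float:
    """Wrap to (−π, π]."""
    while a <= -math.pi:
        a += 2.0 * math.pi
    while a > math.pi:
        a -= 2.0 * math.pi
    return a


@dataclass
class Pose:
    x: float
    y: float
    heading: float  # radians, 0 = +x

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.heading))):
            raise ValueError("pose must be finite")
        self.heading = _wrap_angle(self.heading)

    def mirrored(self) -> "Pose":
        return Pose(self.x, -self.y, -self.heading)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] × [y0, y1] in cm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("rectangle must have positive extent")

    def mirrored(self) -> "Rect":
        return Rect(self.x0, -self.y1, self.x1, -self.y0)


@dataclass
class World:
    obstacles: list[Rect]
    bounds: Rect = field(default_factory=lambda: Rect(-50.0, -300.0, 1000.0, 300.0))
    robot_radius: float = 5.0  # cm
    finish_x: float | None = None  # course completed once the robot passes this line

    def __post_init__(self) -> None:
        if self.robot_radius <= 0:
            raise ValueError("robot_radius must be > 0")
        b = self.bounds
        for r in self.obstacles:
            if not (b.x0 <= r.x0 and r.x1 <= b.x1 and b.y0 <= r.y0 and r.y1 <= b.y1):
                raise ValueError(f"obstacle {r} outside world bounds")


@dataclass(frozen=True)
class SensorRig:
    """Two single-ray sensors at ±half_span from the heading."""

    half_span: float = math.pi / 6.0  # ±30°, a 60° total span
    d_min: float = 15.0
    d_max: float = 30.0


@dataclass(frozen=True)
class MotionParams:
    """Unicycle kinematics of the robot base.

    The drivetrain of the original platform is unpublished; the defaults are
    chosen so that an obstacle first sensed at maximum range leaves an
    untrained controller too little time to commit to a turn while a trained
    one clears it (see docs/methods.md).
    """

    forward_speed: float = 4.0   # cm/s
    turn_rate: float = 0.25      # rad/s
    control_period: float = 100.0  # ms

    def __post_init__(self) -> None:
        if self.forward_speed <= 0 or self.turn_rate <= 0 or self.control_period <= 0:
            raise ValueError("motion parameters must be positive")


def _ray_rect_distance(px: float, py: float, dx: float, dy: float, r: Rect) -> float:
    """Distance along the ray (px,py)+t(dx,dy), t>0, to rectangle r (inf if missed).

    Standard slab intersection; ray origins inside the rectangle return 0.
    """
    tmin, tmax = 0.0, math.inf
    for p, d, lo, hi in ((px, dx, r.x0, r.x1), (py, dy, r.y0, r.y1)):
        if d == 0.0:
            if p < lo or p > hi:
                return math.inf
        else:
            t1 = (lo - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
            if tmin > tmax:
                return math.inf
    return tmin


def sense(world: World, pose: Pose, rig: SensorRig = SensorRig()) -> tuple[float, float]:
    """Range readings (d_left, d_right) in cm, clipped to [d_min, d_max]."""
    b = world.bounds
    if not (b.x0 <= pose.x <= b.x1 and b.y0 <= pose.y <= b.y1):
        raise ValueError("robot pose outside world bounds")
    out = []
    for side in (+1.0, -1.0):  # left ray first
        ang = pose.heading + side * rig.half_span
        dx, dy = math.cos(ang), math.sin(ang)
        d = min(
            (_ray_rect_distance(pose.x, pose.y, dx, dy, r) for r in world.obstacles),
            default=math.inf,
        )
        out.append(min(max(d, rig.d_min), rig.d_max))
    return out[0], out[1]


def robot_step(pose: Pose, mp: MotionParams, cmd: Command, dt_control: float) -> Pose:
    """Advance the unicycle one control period; stop leaves the pose alone."""
    cmd = Command(cmd)
    if cmd is Command.STOP:
        return Pose(pose.x, pose.y, pose.heading)
    dt_s = dt_control / 1000.0
    heading = pose.heading
    if cmd is Command.LEFT:
        heading = _wrap_angle(heading + mp.turn_rate * dt_s)
    elif cmd is Command.RIGHT:
        heading = _wrap_angle(heading - mp.turn_rate * dt_s)
    step = mp.forward_speed * dt_s
    return Pose(pose.x + step * math.cos(heading), pose.y + step * math.sin(heading), heading)


def check_collision(world: World, pose: Pose) -> bool:
    """True iff the robot disc touches any obstacle (closed contact)."""
    r2 = world.robot_radius
    for rect in world.obstacles:
        cx = min(max(pose.x, rect.x0), rect.x1)
        cy = min(max(pose.y, rect.y0), rect.y1)
        if math.hypot(pose.x - cx, pose.y - cy) <= r2:
            return True
    return False


def mirror_world(world: World) -> World:
    return World(
        obstacles=[r.mirrored() for r in world.obstacles],
        bounds=world.bounds.mirrored(),
        robot_radius=world.robot_radius,
        finish_x=world.finish_x,
    )


def make_scenario(name: str) -> tuple[World, Pose]:
    """Deterministic fixtures.

    single_left / single_right: one carton offset to that side of the path,
    intruding just enough that a straight run collides.  slalom5: four
    alternating single cartons followed by one double-width carton spanning
    both sensor rays, where the run must end in a stop.
    """
    if name == "single_left":
        world = World(
            obstacles=[Rect(60.0, 3.0, 80.0, 33.0)],
            finish_x=95.0,
        )
        return world, Pose(0.0, 0.0, 0.0)
    if name == "single_right":
        world, pose = make_scenario("single_left")
        return mirror_world(world), pose.mirrored()
    if name == "slalom5":
        # Alternating single cartons placed along the trained robot's weave
        # (odd obstacles on the left of the path, even on the right), then a
        # double-width carton squarely across the path: both rays see it and
        # the run must end with the brake, not a turn.
        world = World(
            obstacles=[
                Rect(60.0, 3.0, 80.0, 33.0),
                Rect(55.0, -100.0, 100.0, -80.0),
                Rect(180.0, -67.0, 200.0, -37.0),
                Rect(175.0, -177.0, 220.0, -157.0),
                Rect(300.0, -190.0, 320.0, -120.0),
            ],
            bounds=Rect(-50.0, -400.0, 1200.0, 400.0),
        )
        return world, Pose(0.0, 0.0, 0.0)
    raise ValueError(f"unknown scenario {name!r}; valid: single_left, single_right, slalom5")


SCENARIOS = ("single_left", "single_right", "slalom5")


@dataclass
class TrialLog:
    """Per-control-period record of one closed-loop trial."""

    t: list[float] = field(default_factory=list)              # ms, end of period
    d_left: list[float] = field(default_factory=list)
    d_right: list[float] = field(default_factory=list)
    w12: list[float] = field(default_factory=list)
    w34: list[float] = field(default_factory=list)
    gamma12: list[float] = field(default_factory=list)
    gamma34: list[float] = field(default_factory=list)
    r1: list[float] = field(default_factory=list)
    r2: list[float] = field(default_factory=list)
    out_rate: list[float] = field(default_factory=list)
    command: list[str] = field(default_factory=list)
    x: list[float] = field(default_factory=list)
    y: list[float] = field(default_factory=list)
    heading: list[float] = field(default_factory=list)
    releases_r1: list[int] = field(default_factory=list)
    releases_r2: list[int] = field(default_factory=list)
    terminal_cause: str = "timeout"
    collision_time: float | None = None
    stop_time: float | None = None

    COLUMNS = (
        "t", "d_left", "d_right", "w12", "w34", "gamma12", "gamma34",
        "r1", "r2", "out_rate", "command", "x", "y", "heading",
        "releases_r1", "releases_r2",
    )

    @property
    def n_periods(self) -> int:
        return len(self.t)

    def first_release_time(self) -> float | None:
        for t, n1, n2 in zip(self.t, self.releases_r1, self.releases_r2):
            if n1 or n2:
                return t
        return None

    def first_turn_time(self) -> float | None:
        for t, cmd in zip(self.t, self.command):
            if cmd in (Command.LEFT.value, Command.RIGHT.value):
                return t
        return None

    def decision_time(self) -> float | None:
        """Seconds from the first reward release to the first turn command —
        the trial's reaction-time figure of merit."""
        t0, t1 = self.first_release_time(), self.first_turn_time()
        if t0 is None or t1 is None or t1 < t0:
            return None
        return (t1 - t0) / 1000.0


def run_closed_loop(
    spec: NetworkSpec,
    world: World,
    start: Pose,
    mp: MotionParams = MotionParams(),
    max_duration: float = 30.0,
    seed: int | None = None,
    *,
    runtime: NetworkRuntime | None = None,
    rig: SensorRig | None = None,
    sensor_noise_cm: float = 0.0,
) -> TrialLog:
    """Run one trial; returns the TrialLog (terminal cause recorded).

    Passing an existing `runtime` carries network state (weights, learning
    rates, traces) across trials — the memory mechanism of the multi-trial
    protocol.  Sensor noise (uniform jitter) is off by default; when enabled
    it is drawn from a generator seeded with `seed`, keeping runs
    reproducible.
    """
    if rig is None:
        rig = SensorRig(d_min=spec.encoder.d_min, d_max=spec.encoder.d_max)
    if runtime is None:
        runtime = NetworkRuntime(spec)
    rng = None
    if sensor_noise_cm > 0.0:
        import random

        rng = random.Random(seed)
    if not math.isclose(mp.control_period, spec.control_period):
        spec = replace(spec, control_period=mp.control_period)

    log = TrialLog()
    pose = Pose(start.x, start.y, start.heading)
    frozen = False
    n_periods = int(round(max_duration * 1000.0 / mp.control_period))

    # Controller boot: fill the rate-estimation window before the robot
    # moves, otherwise the first decode sees an artificially empty window.
    while runtime.t < spec.rate_window:
        d_left, d_right = sense(world, pose, rig)
        runtime.run_control_period(d_left, d_right)

    b = world.bounds
    for _ in range(n_periods):
        if not (b.x0 <= pose.x <= b.x1 and b.y0 <= pose.y <= b.y1):
            log.terminal_cause = "out_of_bounds"
            break
        d_left, d_right = sense(world, pose, rig)
        if rng is not None:
            d_left = min(max(d_left + rng.uniform(-sensor_noise_cm, sensor_noise_cm), rig.d_min), rig.d_max)
            d_right = min(max(d_right + rng.uniform(-sensor_noise_cm, sensor_noise_cm), rig.d_min), rig.d_max)
        sample = runtime.run_control_period(d_left, d_right)
        cmd = decode_action(sample.out_rate, sample.stop_active, spec.bands)

        log.t.append(sample.t)
        log.d_left.append(d_left)
        log.d_right.append(d_right)
        log.w12.append(sample.w12)
        log.w34.append(sample.w34)
        log.gamma12.append(sample.gamma12)
        log.gamma34.append(sample.gamma34)
        log.r1.append(sample.r1)
        log.r2.append(sample.r2)
        log.out_rate.append(sample.out_rate)
        log.command.append(cmd.value)
        log.releases_r1.append(sample.releases_r1)
        log.releases_r2.append(sample.releases_r2)

        if cmd is Command.STOP:
            log.stop_time = sample.t
            log.terminal_cause = "stop"
            log.x.append(pose.x)
            log.y.append(pose.y)
            log.heading.append(pose.heading)
            break

        if not frozen:
            pose = robot_step(pose, mp, cmd, mp.control_period)
        log.x.append(pose.x)
        log.y.append(pose.y)
        log.heading.append(pose.heading)

        if not frozen and check_collision(world, pose):
            frozen = True
            log.collision_time = sample.t
        if frozen and cmd in (Command.LEFT, Command.RIGHT):
            log.terminal_cause = "collision"
            break
        if world.finish_x is not None and pose.x > world.finish_x:
            log.terminal_cause = "completed"
            break
    else:
        log.terminal_cause = "collision" if frozen else "timeout"

    return log
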