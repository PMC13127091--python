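# stimwell

Design, simulate and quality-control **in vitro direct electrical-stimulation
(ES) devices** — multi-well culture platforms with parallel-plate electrodes
driven by a voltage- or current-controlled source.

`stimwell` is aimed at labs that build or operate such devices and need to
answer, before (and while) stimulating cells:

- What current, electrode voltage, culture-area field and charge does a given
  protocol actually deliver, given the electrode–electrolyte interface?
- Is the protocol inside the electrochemically safe voltage window, or will
  it electrolyse the medium?
- Is the signal source big enough for N wells and M devices?
- Has the device degraded after repeated use?

## The model

A single well is a Randles-type cell: the electrode–electrolyte interface is
a double-layer capacitance C_dl (or, more accurately, a constant phase
element with impedance Z = 1/(Q(jω)ⁿ)) in parallel with a faradaic
charge-transfer resistance R_f, in series with the electrolyte resistance
R_e.  An N-well device composes identical wells in parallel
(voltage-controlled, Z/N) or in series (current-controlled, N·Z).  The
interface time constant τ = R_e·C_dl governs current decay (VC) and
electrode-voltage build-up (CC); per-well quantities follow the monitoring
relations V_R = V_CH2 − V_CH1, I_e = V_R/(R_m·N), V_e = I_e·R_e and
|E_e| = V_e/d.

Around this model the package provides:

| module                | what it does |
|-----------------------|--------------|
| `stimwell.circuit`    | CPE/well/device impedance, lumped equivalents, τ, CPE→C_dl (Brug or Hsu–Mansfeld) |
| `stimwell.eis`        | spectrum simulation, Bode views, complex nonlinear least-squares fitting, life-cycle QC |
| `stimwell.protocol`   | waveform specs, exact piecewise-exponential transient simulation (VC and CC), charge accounting, field dosimetry |
| `stimwell.cv`         | cyclic-voltammetry window-expansion analysis and protocol safety checks |
| `stimwell.monitor`    | reduction of two-channel oscilloscope captures to delivered per-well signals |
| `stimwell.design`     | source-sizing arithmetic (loads, compliance voltage, device counts) |
| `stimwell.synth`      | seeded synthetic EIS/CV/scope data from known ground truth |
| `stimwell.io` / `cli` | CSV dialects, YAML run configs, `stimwell` command-line tool |

## Worked example

An 8-well micro-dish with nanocolumnar Pt electrodes (R_e = 250 Ω,
R_f = 100 kΩ, C_dl = 10 µF per well, 10 mm electrode gap) stimulated in
voltage-controlled mode with 1 V biphasic pulses at 100 Hz, 25 % duty per
phase:

```python
import stimwell as sw

well = sw.WellParams(r_e=250.0, r_f=1e5, c_dl=1e-5)
dev = sw.DeviceModel(well=well, n_wells=8, wiring="parallel", spacing_d_mm=10.0)
print(f"tau = {sw.time_constant(well)*1e3:.1f} ms")

wf = sw.WaveformSpec(shape="biphasic_symmetric", amplitude=1.0,
                     frequency=100.0, duty_percent=25.0)
sim = sw.simulate_vc(dev, sw.SourceSpec(mode="voltage_controlled"),
                     sw.MonitorSpec(r_m=50.0), wf, duration=0.03, dt=1e-6)
print(f"peak per-well current = {sim.i_e.max()*1e3:.3f} mA")
print(f"peak field = {sim.e_mag.max():.1f} mV/mm")

cs = sw.charge_summary(sim, wf)
print(f"first-pulse Q_inj = {cs.q_inj[0]*1e6:.2f} uC")

ok = sw.check_safety(sim, sw.SafetyWindow(v_min=-1.0, v_max=1.3)).safe
print(f"inside the Pt safe window: {ok}")
```

Output:

```
tau = 2.5 ms
peak per-well current = 0.989 mA
peak field = 24.7 mV/mm
first-pulse Q_inj = 2.12 uC
inside the Pt safe window: True
```

The first pulse starts at 1 V over the loop resistance seen by one well
(8·(50+50) + 250 = 1050 Ω, i.e. 0.952 mA; later pulses peak slightly higher
because the double layer is left negatively charged by the preceding
counterphase).  Within each pulse the current decays as the double layer
charges, so the delivered field stays below the 1 V / 10 mm ceiling of
100 mV/mm, and the per-well electrode voltage never leaves the −1…+1.3 V Pt
safe window.

The same calculations are available from the shell, e.g.

```bash
stimwell design --r-well 330 --n 8 --wiring series --i-deliver 0.003 --n-devices 4
stimwell simulate --config device.yaml --out trace.csv
stimwell cv-window cv_scan.csv
```

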