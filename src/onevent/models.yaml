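# Shipped point-model parameterizations.
#
# Membrane conductances in S/cm^2, reversals in mV, Cm in uF/cm^2.
# Synaptic weights in uS (peak conductance increment per event), taus in ms.
# reference_rate_hz is the published average firing rate of each
# parameterization under its Poisson drive, kept for calibration checks.
#
# The compartment defaults to a 10 um x 10 um cylinder (area handled in
# code); synaptic reversals default to 0 mV (exc) / -75 mV (inh).

base:
  model_kind: hh
  membrane: &hh_membrane
    gNa: 0.12
    gK: 0.036
    gL: 0.0003
    ENa: 50.0
    EK: -77.0
    EL: -54.3
    Cm: 1.0
  synapse:
    weight_exc: 0.0002
    weight_inh: 0.0005
    tau_exc: 2.0
    tau_inh: 6.0
  reference_rate_hz: 22.14

lw:
  model_kind: hh
  membrane: *hh_membrane
  synapse:
    weight_exc: 0.00015
    weight_inh: 0.0002
    tau_exc: 2.0
    tau_inh: 6.0
  reference_rate_hz: 13.94

lt:
  model_kind: hh
  membrane: *hh_membrane
  synapse:
    weight_exc: 0.0002
    weight_inh: 0.0005
    tau_exc: 10.0
    tau_inh: 40.0
  reference_rate_hz: 17.62

lwlt:
  model_kind: hh
  membrane: *hh_membrane
  synapse:
    weight_exc: 0.00015
    weight_inh: 0.0002
    tau_exc: 10.0
    tau_inh: 40.0
  reference_rate_hz: 23.10

burst:
  model_kind: hh
  membrane: *hh_membrane
  synapse:
    weight_exc: 0.0001
    weight_inh: 0.0005
    tau_exc: 40.0
    tau_inh: 20.0
  reference_rate_hz: 30.07

wb:
  model_kind: wb
  membrane:
    gNa: 0.035
    gK: 0.009
    gL: 0.0001
    ENa: 55.0
    EK: -90.0
    EL: -65.0
    Cm: 1.0
  synapse:
    weight_exc: 0.00003
    weight_inh: 0.00005
    tau_exc: 2.0
    tau_inh: 6.0
  reference_rate_hz: 25.03
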