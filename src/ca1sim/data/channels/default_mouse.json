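{
 "channels": [
  {
   "name": "Nax",
   "gates": [
    {
     "name": "m",
     "power": 3,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -38.0,
      "slope": 6.0,
      "tau_min": 0.03,
      "tau_amp": 0.3,
      "tau_vhalf": -38.0,
      "tau_sigma": 15.0
     }
    },
    {
     "name": "h",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -50.0,
      "slope": -4.0,
      "tau_min": 0.2,
      "tau_amp": 8.0,
      "tau_vhalf": -45.0,
      "tau_sigma": 10.0,
      "floor": 0.0
     }
    }
   ],
   "reversal": 55.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "Na3",
   "gates": [
    {
     "name": "m",
     "power": 3,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -35.0,
      "slope": 6.0,
      "tau_min": 0.05,
      "tau_amp": 0.4,
      "tau_vhalf": -35.0,
      "tau_sigma": 15.0
     }
    },
    {
     "name": "h",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -48.0,
      "slope": -4.0,
      "tau_min": 0.2,
      "tau_amp": 8.0,
      "tau_vhalf": -45.0,
      "tau_sigma": 10.0,
      "floor": 0.0
     }
    }
   ],
   "reversal": 55.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "KDR",
   "gates": [
    {
     "name": "n",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -12.0,
      "slope": 11.0,
      "tau_min": 0.5,
      "tau_amp": 3.0,
      "tau_vhalf": -10.0,
      "tau_sigma": 20.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "KAp",
   "gates": [
    {
     "name": "n",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": 5.0,
      "slope": 11.0,
      "tau_min": 0.2,
      "tau_amp": 1.0,
      "tau_vhalf": -30.0,
      "tau_sigma": 20.0
     }
    },
    {
     "name": "l",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -56.0,
      "slope": -6.0,
      "tau_min": 2.0,
      "tau_amp": 20.0,
      "tau_vhalf": -60.0,
      "tau_sigma": 20.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "KAd",
   "gates": [
    {
     "name": "n",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -5.0,
      "slope": 11.0,
      "tau_min": 0.2,
      "tau_amp": 1.0,
      "tau_vhalf": -40.0,
      "tau_sigma": 20.0
     }
    },
    {
     "name": "l",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -56.0,
      "slope": -6.0,
      "tau_min": 2.0,
      "tau_amp": 20.0,
      "tau_vhalf": -60.0,
      "tau_sigma": 20.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "KM",
   "gates": [
    {
     "name": "m",
     "power": 1,
     "form": "borg_graham",
     "parameters": {
      "vhalf_l": -35.0,
      "vhalf_t": -35.0,
      "a0t": 0.01,
      "zeta_l": -4.0,
      "zeta_t": -4.0,
      "gmt": 0.5,
      "tau_min": 30.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "KD",
   "gates": [
    {
     "name": "n",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -20.0,
      "slope": 9.0,
      "tau_min": 5.0,
      "tau_amp": 100.0,
      "tau_vhalf": -50.0,
      "tau_sigma": 20.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "CaN",
   "gates": [
    {
     "name": "m",
     "power": 2,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -14.0,
      "slope": 7.0,
      "tau_min": 0.5,
      "tau_amp": 2.0,
      "tau_vhalf": -20.0,
      "tau_sigma": 15.0
     }
    }
   ],
   "reversal": "calcium",
   "calcium_flux_fraction": 1.0
  },
  {
   "name": "CaL",
   "gates": [
    {
     "name": "m",
     "power": 2,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -10.0,
      "slope": 6.0,
      "tau_min": 4.0,
      "tau_amp": 8.0,
      "tau_vhalf": -20.0,
      "tau_sigma": 15.0
     }
    }
   ],
   "reversal": "calcium",
   "calcium_flux_fraction": 1.0
  },
  {
   "name": "CaT",
   "gates": [
    {
     "name": "m",
     "power": 2,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -35.0,
      "slope": 6.0,
      "tau_min": 1.0,
      "tau_amp": 4.0,
      "tau_vhalf": -40.0,
      "tau_sigma": 15.0
     }
    },
    {
     "name": "h",
     "power": 1,
     "form": "inf_tau",
     "parameters": {
      "vhalf": -65.0,
      "slope": -5.0,
      "tau_min": 5.0,
      "tau_amp": 30.0,
      "tau_vhalf": -70.0,
      "tau_sigma": 15.0
     }
    }
   ],
   "reversal": "calcium",
   "calcium_flux_fraction": 1.0
  },
  {
   "name": "KCa",
   "gates": [
    {
     "name": "q",
     "power": 1,
     "form": "calcium_hill",
     "parameters": {
      "k_half": 0.001,
      "hill": 2,
      "tau": 20.0
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "Cagk",
   "gates": [
    {
     "name": "o",
     "power": 1,
     "form": "borg_graham",
     "parameters": {
      "vhalf_l": -20.0,
      "vhalf_t": -20.0,
      "a0t": 0.4,
      "zeta_l": -8.0,
      "zeta_t": -8.0,
      "gmt": 0.5,
      "tau_min": 0.5,
      "ca_shift_per_decade": -40.0,
      "ca_ref": 0.001
     }
    }
   ],
   "reversal": -90.0,
   "calcium_flux_fraction": 0.0
  },
  {
   "name": "Ih",
   "gates": [
    {
     "name": "h",
     "power": 1,
     "form": "borg_graham",
     "parameters": {
      "vhalf_l": -77.46,
      "vhalf_t": -70.24,
      "a0t": 0.0047,
      "zeta_l": 3.5,
      "zeta_t": 7.3,
      "gmt": 0.145,
      "clk": 0.24
     }
    }
   ],
   "reversal": -30.0,
   "calcium_flux_fraction": 0.0
  }
 ]
}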