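# Reference table of 36 athlete observers: experimental vs simulated 2AFC angular
# thresholds (deg), psychometric slopes (1/deg) and mean reaction times (s),
# with the four model parameters (k, tau, delta, tau_a) used for each group.
# Grouped observers share identical simulated values and parameters (ditto=1 marks
# rows whose simulated columns repeat the group leader's). suspect=1 flags values
# transcribed verbatim from the source despite being probable typos (A03 delta).
subject,thr_exp,thr_exp_err,thr_sim,thr_sim_err,slope_exp,slope_exp_err,slope_sim,slope_sim_err,rt_exp,rt_exp_err,rt_sim,rt_sim_err,k,tau,delta,tau_a,ditto,suspect
C12,4.041,1.06,5.252,0.20,0.261,0.030,0.263,0.0049,0.994,0.07,1.148,0.0005,4,0.025,0.022,1.22,0,0
A10,4.176,1.08,5.252,0.20,0.252,0.029,0.263,0.0049,0.929,0.04,1.148,0.0005,4,0.025,0.022,1.22,1,0
B04,4.506,1.11,5.252,0.20,0.246,0.028,0.263,0.0049,1.194,0.05,1.148,0.0005,4,0.025,0.022,1.22,1,0
B01,4.805,1.13,5.252,0.20,0.243,0.027,0.263,0.0049,1.443,0.06,1.148,0.0005,4,0.025,0.022,1.22,1,0
A15,5.321,1.15,5.317,0.19,0.242,0.025,0.276,0.005,1.131,0.08,1.106,0.0002,2,0.033,0.032,1.34,0,0
B05,5.361,1.05,5.201,0.18,0.284,0.028,0.307,0.0055,1.165,0.01,1.146,0.0002,4,0.037,0.030,1.40,0,0
B09,6.602,1.42,6.872,0.27,0.188,0.021,0.180,0.0036,1.001,0.03,1.020,0.0003,4,0.025,0.034,1.22,0,0
A11,6.637,1.52,6.872,0.27,0.171,0.023,0.180,0.0036,1.013,0.05,1.020,0.0003,4,0.025,0.034,1.22,1,0
A06,6.609,1.22,6.793,0.25,0.233,0.020,0.200,0.0038,0.989,0.03,0.883,0.0002,8,0.033,0.032,1.10,0,0
A01,7.000,1.52,6.909,0.25,0.175,0.02,0.205,0.0038,1.007,0.01,1.089,0.0003,8,0.030,0.034,1.40,0,0
C07,7.097,1.42,6.909,0.25,0.192,0.02,0.205,0.0038,1.169,0.07,1.089,0.0003,8,0.030,0.034,1.40,1,0
C11,7.165,1.39,6.909,0.25,0.197,0.02,0.205,0.0038,1.146,0.08,1.089,0.0003,8,0.030,0.034,1.40,1,0
B14,7.692,1.80,7.701,0.36,0.147,0.018,0.131,0.0032,1.005,0.04,1.076,0.0009,1,0.024,0.026,0.96,0,0
B08,7.753,1.81,7.701,0.36,0.146,0.018,0.131,0.0032,0.923,0.06,1.076,0.0009,1,0.024,0.026,0.96,1,0
A02,7.837,1.87,7.701,0.36,0.141,0.018,0.131,0.0032,1.133,0.04,1.076,0.0009,1,0.024,0.026,0.96,1,0
A13,7.873,1.69,7.701,0.36,0.159,0.018,0.131,0.0032,1.203,0.08,1.076,0.0009,1,0.024,0.026,0.96,1,0
B11,8.132,2.00,8.459,0.39,0.132,0.017,0.124,0.0031,1.065,0.02,1.116,0.0009,1,0.024,0.028,1.00,0,0
C13,8.594,2.09,8.459,0.39,0.128,0.017,0.124,0.0031,1.147,0.05,1.116,0.0009,1,0.024,0.028,1.00,1,0
C04,9.173,1.78,9.685,0.35,0.158,0.017,0.148,0.003,0.887,0.03,0.880,0.0003,16,0.025,0.034,1.04,0,0
B03,9.191,2.64,9.292,0.45,0.103,0.016,0.111,0.0029,1.141,0.07,1.181,0.0012,2,0.024,0.028,1.00,0,0
C06,9.543,2.34,9.709,0.41,0.118,0.016,0.123,0.0029,0.899,0.05,1.078,0.001,2,0.024,0.030,0.90,0,0
B07,9.589,2.86,9.709,0.41,0.096,0.016,0.123,0.0029,1.264,0.07,1.078,0.001,2,0.024,0.030,0.90,1,0
C08,9.747,1.70,9.838,0.32,0.170,0.017,0.167,0.0031,0.947,0.05,0.944,0.0003,32,0.033,0.032,1.22,0,0
A03,10.490,1.56,12.076,0.43,0.130,0.011,0.130,0.0028,0.964,0.04,0.858,0.0006,32,0.025,0.340,0.88,0,1
A04,10.801,2.20,12.076,0.43,0.132,0.016,0.130,0.0028,0.757,0.05,0.858,0.0006,32,0.025,0.340,0.88,1,1
A07,10.843,2.26,12.076,0.43,0.128,0.016,0.130,0.0028,0.871,0.05,0.858,0.0006,32,0.025,0.340,0.88,1,1
A05,10.770,2.72,10.747,0.41,0.105,0.015,0.130,0.0029,1.098,0.06,1.068,0.0014,4,0.024,0.028,0.80,0,0
C01,10.830,2.61,10.747,0.41,0.110,0.016,0.130,0.0029,0.909,0.06,1.068,0.0014,4,0.024,0.028,0.80,1,0
A08,12.132,2.76,12.722,0.45,0.109,0.015,0.124,0.0027,0.793,0.03,0.962,0.0013,4,0.024,0.032,0.66,0,0
B02,12.173,2.68,12.722,0.45,0.113,0.015,0.124,0.0027,0.936,0.05,0.962,0.0013,4,0.024,0.032,0.66,1,0
B06,12.525,2.82,12.722,0.45,0.108,0.015,0.124,0.0027,0.888,0.06,0.962,0.0013,4,0.024,0.032,0.66,1,0
B13,12.860,3.94,11.549,0.49,0.078,0.015,0.109,0.0028,1.032,0.06,1.067,0.0011,2,0.024,0.034,0.84,0,0
B10,13.160,3.02,13.363,0.56,0.103,0.015,0.101,0.0027,1.044,0.06,1.208,0.0009,64,0.025,0.036,1.15,0,0
A14,16.617,4.89,17.319,0.74,0.071,0.014,0.088,0.0025,1.058,0.06,1.154,0.0017,4,0.024,0.038,0.60,0,0
A09,17.194,5.84,17.319,0.74,0.061,0.014,0.088,0.0025,1.014,0.04,1.154,0.0017,4,0.024,0.038,0.60,1,0
C02,17.787,5.36,17.319,0.74,0.068,0.014,0.088,0.0025,0.842,0.04,1.154,0.0017,4,0.024,0.038,0.60,1,0
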