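section,scan,beam_width_mm,dpi_cGycm,ctdi_w_cGy,dlp_cGycm,f0_cGy,method,mean_peripheral_cGy
profile,head,20,17.48,8.73,17.48,3.68,mc,
profile,head,34,29.72,8.75,29.72,4.68,mc,
profile,head,46,40.21,8.75,40.20,5.32,mc,
profile,head,60,52.45,8.75,52.44,5.96,mc,
profile,head,72,62.94,8.75,62.93,6.44,mc,
profile,head,84,73.43,8.74,73.42,6.82,mc,
profile,head,98,85.66,8.75,85.65,7.20,mc,
profile,head,110,96.15,8.74,96.14,7.49,mc,
profile,head,124,108.39,8.73,108.38,7.74,mc,
profile,head,136,118.88,8.72,118.86,7.99,mc,
profile,body,22,9.38,4.26,9.37,0.84,mc,
profile,body,38,16.20,4.26,16.19,1.17,mc,
profile,body,52,22.16,4.26,22.15,1.44,mc,
profile,body,66,28.13,4.27,28.12,1.67,mc,
profile,body,80,34.10,4.27,34.08,1.88,mc,
profile,body,96,40.92,4.26,40.90,2.08,mc,
profile,body,110,46.88,4.27,46.86,2.27,mc,
profile,body,124,52.85,4.26,52.82,2.39,mc,
profile,body,138,58.82,4.26,58.79,2.55,mc,
profile,body,154,65.64,4.25,65.60,2.65,mc,
mean,head,,,8.74,,,mc,
mean,body,,,4.26,,,mc,
point_dose,head,206,,8.50,,8.78,measured,8.21
point_dose,head,206,,8.77,,8.77,mc,8.76
point_dose,body,206,,4.21,,3.09,measured,5.32
point_dose,body,206,,4.26,,3.08,mc,5.44
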