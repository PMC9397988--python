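bmi_class,traction_level,T12-L1,L1-L2,L2-L3,L3-L4,L4-L5,L5-S
normal,5,0.147E-02,0.562E-02,0.749E-02,0.617E-02,0.418E-02,0.190E-02
normal,7,0.718E-02,3.595E-02,5.649E-02,4.362E-02,3.300E-02,1.448E-02
normal,9,1.642E-02,5.837E-02,9.232E-02,7.939E-02,6.654E-02,4.289E-02
overweight,5,0.106E-02,0.302E-02,0.306E-02,0.249E-02,0.186E-02,0.0787E-02
overweight,7,0.531E-02,2.168E-02,3.104E-02,2.593E-02,2.031E-02,1.050E-02
overweight,9,1.204E-02,5.388E-02,7.949E-02,6.659E-02,5.503E-02,2.756E-02
moderate_obese,5,0.120E-02,0.190E-02,0.170E-02,0.127E-02,0.107E-02,0.0647E-02
moderate_obese,7,0.514E-02,1.61E-02,2.13E-02,1.68E-02,1.42E-02,0.930E-02
moderate_obese,9,0.993E-02,3.29E-02,4.55E-02,3.71E-02,3.24E-02,2.33E-02
extreme_obese,5,8.09E-06,6.30E-06,5.75E-06,5.04E-06,4.39E-06,4.51E-06
extreme_obese,7,0.239E-02,0.709E-02,0.618E-02,0.464E-02,0.440E-02,0.403E-02
extreme_obese,9,0.399E-02,1.35E-02,1.89E-02,1.56E-02,1.41E-02,1.07E-02
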