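species,architecture,method,map50
cow,yolov5,visible,0.89
cow,yolov5,thermal,0.77
cow,yolov5,guided_filter,0.83
cow,yolov5,laplacian,0.88
cow,yolov5,svd,0.16
cow,yolov5,sparse,0.93
cow,yolov5,gradient,0.69
cow,yolov5,tvm,0.84
cow,yolov5,wl_swarm,0.86
cow,yolov5,wl_tvm,0.74
deer,yolov5,visible,0.63
deer,yolov5,thermal,0.64
deer,yolov5,guided_filter,0.56
deer,yolov5,laplacian,0.66
deer,yolov5,svd,0.01
deer,yolov5,sparse,0.72
deer,yolov5,gradient,0.69
deer,yolov5,tvm,0.77
deer,yolov5,wl_swarm,0.70
deer,yolov5,wl_tvm,0.62
horse,yolov5,visible,0.99
horse,yolov5,thermal,0.97
horse,yolov5,guided_filter,1.00
horse,yolov5,laplacian,0.95
horse,yolov5,svd,0.89
horse,yolov5,sparse,0.99
horse,yolov5,gradient,0.95
horse,yolov5,tvm,0.95
horse,yolov5,wl_swarm,0.95
horse,yolov5,wl_tvm,0.96
cow,yolov7,visible,0.26
cow,yolov7,thermal,0.48
cow,yolov7,guided_filter,0.49
cow,yolov7,laplacian,0.37
cow,yolov7,svd,0.10
cow,yolov7,sparse,0.59
cow,yolov7,gradient,0.55
cow,yolov7,tvm,0.00
cow,yolov7,wl_swarm,0.47
cow,yolov7,wl_tvm,0.60
deer,yolov7,visible,0.00
deer,yolov7,thermal,0.51
deer,yolov7,guided_filter,0.50
deer,yolov7,laplacian,0.85
deer,yolov7,svd,0.00
deer,yolov7,sparse,0.37
deer,yolov7,gradient,0.62
deer,yolov7,tvm,0.00
deer,yolov7,wl_swarm,0.44
deer,yolov7,wl_tvm,0.46
horse,yolov7,visible,0.53
horse,yolov7,thermal,0.47
horse,yolov7,guided_filter,0.44
horse,yolov7,laplacian,0.44
horse,yolov7,svd,0.24
horse,yolov7,sparse,0.64
horse,yolov7,gradient,0.54
horse,yolov7,tvm,0.52
horse,yolov7,wl_swarm,0.50
horse,yolov7,wl_tvm,0.54
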